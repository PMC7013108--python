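{
 "coef_full": [
  -2.0574999999999997,
  2.7125,
  0.42749999999999977
 ],
 "dispersion_full": 64.53736779055477,
 "note": "synthetic reference output, computed once by the LP route in scripts/make_rank_fixture.py",
 "table": [
  {
   "F": 16.76468271108466,
   "df1": 1,
   "df2": 25,
   "p": 0.0003885769430028028,
   "term": "sex"
  },
  {
   "F": 27.26283664334506,
   "df1": 1,
   "df2": 25,
   "p": 2.1039583784632367e-05,
   "term": "phenotype"
  },
  {
   "F": 0.9543776302054883,
   "df1": 1,
   "df2": 25,
   "p": 0.33796676799198994,
   "term": "sex:phenotype"
  }
 ],
 "tau": 2.6545184013361602
}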