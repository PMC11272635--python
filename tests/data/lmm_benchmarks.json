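{
 "_reference": "fixed-effect estimates, SEs, Satterthwaite df and likelihoods computed with lmerTest 3.1-3 / lme4 1.1-37 on R 4.3.3; datasets are regenerated deterministically by tests/conftest.py",
 "term_order": [
  "intercept",
  "tilt_deg",
  "aiis_type[I]",
  "femoral_version",
  "acetabular_version",
  "lcea"
 ],
 "benchmarks": {
  "bench_default": {
   "terms": [
    "(Intercept)",
    "tilt_deg",
    "aiis_typeI",
    "femoral_version",
    "acetabular_version",
    "lcea"
   ],
   "beta": [
    54.153779031043,
    -0.712313493328,
    -8.636336035541,
    -0.8020603941636,
    -0.1250581682143,
    -0.06225111660615
   ],
   "se": [
    10.950361104361,
    0.08157963574779,
    4.051919937409,
    0.2335765602621,
    0.3393922628715,
    0.3248895112447
   ],
   "df": [
    72.999997481062,
    155.000000509843,
    72.999998701747,
    72.999998712659,
    72.999998732204,
    72.999997461183
   ],
   "var_intercept": 246.254858699436,
   "var_residual": 103.821696712376,
   "reml_loglik": -952.592135442007,
   "ml_deviance": 1907.5949908436,
   "bic_ml": 1951.237559766461
  },
  "bench_small": {
   "terms": [
    "(Intercept)",
    "tilt_deg",
    "aiis_typeI",
    "femoral_version",
    "acetabular_version",
    "lcea"
   ],
   "beta": [
    15.206333107468,
    -0.706068149397,
    -9.256300921434,
    -0.6614889133415,
    -0.07209676330597,
    0.974944740995
   ],
   "se": [
    10.153043738201,
    0.1519594733467,
    3.525676422724,
    0.1913563587234,
    0.312953420792,
    0.3367685905529
   ],
   "df": [
    25.000000044676,
    58.99999998345,
    25.000000014946,
    25.000000015924,
    25.000000011048,
    25.000000054751
   ],
   "var_intercept": 35.800844406008,
   "var_residual": 138.550089238862,
   "reml_loglik": -353.822509716266,
   "ml_deviance": 709.958944873192,
   "bic_ml": 745.957422235834
  },
  "bench_finegrid": {
   "terms": [
    "(Intercept)",
    "tilt_deg",
    "aiis_typeI",
    "femoral_version",
    "acetabular_version",
    "lcea"
   ],
   "beta": [
    15.75705071391,
    -0.5634972566373,
    -1.914900451778,
    -0.3833915900198,
    0.5686963093,
    0.4301660074178
   ],
   "se": [
    12.394157914253,
    0.09377803239221,
    4.562734038425,
    0.2300772323567,
    0.343426649992,
    0.3220429347252
   ],
   "df": [
    45.000000167197,
    199.000000125743,
    44.99999969152,
    44.99999970909,
    44.999999887007,
    44.999999924475
   ],
   "var_intercept": 181.791988560204,
   "var_residual": 109.928991991936,
   "reml_loglik": -993.235105622678,
   "ml_deviance": 1989.489060079956,
   "bic_ml": 2033.660747422854
  },
  "bench_highvar": {
   "terms": [
    "(Intercept)",
    "tilt_deg",
    "aiis_typeI",
    "femoral_version",
    "acetabular_version",
    "lcea"
   ],
   "beta": [
    10.815270997763,
    -0.7116334741373,
    -7.875477532289,
    -0.7253400037291,
    -0.4117035473505,
    1.363250712847
   ],
   "se": [
    43.478281456864,
    0.07732768668392,
    14.53810509782,
    0.5361137375688,
    1.022553799793,
    1.188656935115
   ],
   "df": [
    15.000771841106,
    38.999739412083,
    15.000772352079,
    15.000772213464,
    15.000772272428,
    15.000771971425
   ],
   "var_intercept": 882.772440192917,
   "var_residual": 23.918284511545,
   "reml_loglik": -217.519238552566,
   "ml_deviance": 448.305571608133,
   "bic_ml": 481.06032810591
  },
  "bench_unbalanced": {
   "terms": [
    "(Intercept)",
    "tilt_deg",
    "aiis_typeI",
    "femoral_version",
    "acetabular_version",
    "lcea"
   ],
   "beta": [
    26.120003001796,
    -0.5226937912056,
    -9.424828259266,
    -1.049395237949,
    -0.3199820559904,
    1.064323160338
   ],
   "se": [
    18.20200517745,
    0.1356724197533,
    5.530645660758,
    0.2803293052231,
    0.4521024422546,
    0.4398152711183
   ],
   "df": [
    34.506404987217,
    59.062395936448,
    34.373823374926,
    36.061700986318,
    33.174783591565,
    35.345325482558
   ],
   "var_intercept": 193.078023119162,
   "var_residual": 112.993763306574,
   "reml_loglik": -400.919313485457,
   "ml_deviance": 807.749564239609,
   "bic_ml": 844.510523040686
  }
 }
}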