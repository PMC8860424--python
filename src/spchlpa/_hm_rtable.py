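"""Frozen lookup table for the correlated-AUC z-test.

r = Corr(AUC1_hat, AUC2_hat) tabulated against the average
within-class rank correlation of the two score sets (rows) and
the average AUC (columns), computed once by Monte Carlo under
the equal-AUC binormal ROC model (synthetic reconstruction).
"""

import numpy as np

RANK_CORR_GRID = np.array([0.    , 0.0938, 0.1885, 0.2839, 0.3783, 0.4752, 0.5738, 0.6738, 0.7767,
 0.8827, 1.    ])

AUC_GRID = np.array([0.5  , 0.55 , 0.6  , 0.65 , 0.7  , 0.75 , 0.8  , 0.85 , 0.9  , 0.95 ,
 0.975])

R_TABLE = np.array(
[[0.    , 0.    , 0.    , 0.    , 0.    , 0.    , 0.    , 0.    , 0.    ,
  0.    , 0.    ],
 [0.0887, 0.0876, 0.1043, 0.1007, 0.1275, 0.1143, 0.0658, 0.0693, 0.0564,
  0.0448, 0.0485],
 [0.2019, 0.2058, 0.1729, 0.1903, 0.1623, 0.162 , 0.1777, 0.1488, 0.1721,
  0.1198, 0.1097],
 [0.2918, 0.2858, 0.2945, 0.306 , 0.289 , 0.2906, 0.249 , 0.25  , 0.2551,
  0.1702, 0.1807],
 [0.3944, 0.3619, 0.3809, 0.3721, 0.3587, 0.3778, 0.3458, 0.3449, 0.3173,
  0.2883, 0.2644],
 [0.4561, 0.4584, 0.4447, 0.4624, 0.4589, 0.4612, 0.4517, 0.4484, 0.4167,
  0.3813, 0.3257],
 [0.5732, 0.595 , 0.5837, 0.5752, 0.5502, 0.5592, 0.5565, 0.5367, 0.5223,
  0.4365, 0.4221],
 [0.6825, 0.6772, 0.6754, 0.6676, 0.6719, 0.673 , 0.6453, 0.6485, 0.6159,
  0.6082, 0.5225],
 [0.7874, 0.7818, 0.7741, 0.7779, 0.7744, 0.766 , 0.758 , 0.7541, 0.7424,
  0.7202, 0.6506],
 [0.8846, 0.8862, 0.8919, 0.8867, 0.8898, 0.8876, 0.8756, 0.8727, 0.8621,
  0.8426, 0.8149],
 [1.    , 1.    , 1.    , 1.    , 1.    , 1.    , 1.    , 1.    , 1.    ,
  1.    , 1.    ]]
)
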