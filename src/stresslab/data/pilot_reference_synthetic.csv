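participant_id,group,d1,d2,d3,d4,d5
pilot001,pilot,85.193,18.981,29.558,40.766,40.381
pilot002,pilot,53.14,50.7,38.029,35.712,66.13
pilot003,pilot,42.795,63.945,16.77,22.144,67.215
pilot004,pilot,34.905,29.278,30.553,38.267,43.777
pilot005,pilot,77.993,25.547,51.096,17.919,40.548
pilot006,pilot,64.227,35.748,28.394,37.494,79.943
pilot007,pilot,67.422,17.847,6.048,37.579,49.425
pilot008,pilot,1.097,19.391,28.781,19.899,21.116
pilot009,pilot,76.712,31.491,42.404,38.683,26.186
pilot010,pilot,13.651,2.851,38.619,39.313,30.802
pilot011,pilot,51.556,26.442,30.12,34.909,40.756
pilot012,pilot,98.086,49.562,21.518,42.291,95.448
pilot013,pilot,21.076,52.416,63.914,51.617,77.25
pilot014,pilot,43.51,10.591,90.86,43.673,47.387
pilot015,pilot,82.913,58.877,13.806,19.117,39.957
pilot016,pilot,74.756,64.889,37.229,29.866,18.083
pilot017,pilot,71.983,82.225,39.332,16.822,39.637
pilot018,pilot,27.366,46.38,24.384,27.082,28.211
pilot019,pilot,53.583,33.047,62.688,36.987,54.392
pilot020,pilot,7.01,45.022,53.604,42.741,52.192
pilot021,pilot,57.562,49.619,11.404,21.318,37.233
pilot022,pilot,65.532,35.796,53.821,52.04,95.361
pilot023,pilot,35.961,66.024,41.255,30.077,57.771
pilot024,pilot,36.865,60.993,58.241,61.972,52.533
pilot025,pilot,64.637,49.032,52.709,19.941,26.964
pilot026,pilot,83.886,62.361,45.675,53.502,50.586
pilot027,pilot,73.671,38.871,38.554,37.47,15.201
pilot028,pilot,51.477,63.64,61.424,28.106,33.885
pilot029,pilot,22.9,36.6,19.087,44.503,94.454
pilot030,pilot,60.788,55.206,52.354,28.104,26.062
pilot031,pilot,65.115,8.647,37.422,40.243,97.279
pilot032,pilot,48.267,76.146,72.089,53.239,40.682
pilot033,pilot,44.963,27.006,28.348,56.235,62.663
pilot034,pilot,36.529,39.578,36.03,53.002,61.881
pilot035,pilot,19.319,52.787,31.357,47.336,49.851
pilot036,pilot,63.012,83.286,36.066,23.76,53.616
pilot037,pilot,55.342,43.09,29.972,69.266,55.991
pilot038,pilot,24.247,28.952,36.49,44.788,68.364
pilot039,pilot,15.458,34.336,36.426,21.28,47.331
pilot040,pilot,25.811,31.033,69.914,45.397,56.662
pilot041,pilot,34.716,35.211,46.142,51.182,36.339
pilot042,pilot,31.76,44.206,21.49,88.132,41.993
pilot043,pilot,57.98,19.92,39.345,49.909,65.997
pilot044,pilot,20.269,39.781,45.113,34.334,49.024
pilot045,pilot,52.445,11.826,44.021,75.632,95.046
pilot046,pilot,35.169,14.055,60.841,28.456,31.325
pilot047,pilot,52.798,17.304,42.206,18.574,65.326
pilot048,pilot,21.912,85.175,28.669,65.539,22.222
pilot049,pilot,39.374,65.427,31.423,44.376,37.643
pilot050,pilot,45.344,71.424,65.352,58.825,51.437
pilot051,pilot,14.571,69.665,51.568,55.197,46.075
pilot052,pilot,11.275,28.822,14.743,50.106,40.078
pilot053,pilot,33.48,31.189,50.248,28.356,51.597
pilot054,pilot,37.033,19.429,41.916,31.159,16.015
pilot055,pilot,50.027,35.149,44.225,36.178,53.823
pilot056,pilot,54.107,26.824,40.406,92.771,61.524
pilot057,pilot,46.08,38.064,39.095,49.667,43.451
pilot058,pilot,41.101,24.496,67.574,43.686,33.199
pilot059,pilot,36.285,87.195,33.159,51.047,84.94
pilot060,pilot,11.763,17.121,38.713,54.026,45.085
pilot061,pilot,44.823,30.698,36.475,56.01,18.602
pilot062,pilot,44.446,44.269,51.488,20.562,44.69
pilot063,pilot,19.32,27.59,45.323,56.505,30.922
pilot064,pilot,48.539,33.756,40.863,46.21,29.394
pilot065,pilot,54.978,33.473,61.105,48.904,40.545
pilot066,pilot,38.539,47.354,37.623,49.223,24.946
pilot067,pilot,64.178,51.294,49.256,27.203,46.416
pilot068,pilot,54.105,64.025,32.313,33.865,76.334
pilot069,pilot,61.759,39.821,62.379,1.062,5.118
pilot070,pilot,25.848,58.834,23.23,27.079,59.379
pilot071,pilot,42.063,53.782,52.37,41.01,59.816
pilot072,pilot,40.267,25.123,38.316,47.14,47.703
pilot073,pilot,36.044,43.31,49.777,32.233,58.995
pilot074,pilot,38.571,44.082,6.858,28.138,46.599
pilot075,pilot,36.829,58.483,69.102,65.44,46.439
pilot076,pilot,24.468,47.342,39.68,66.034,80.936
pilot077,pilot,26.024,48.253,33.598,15.661,48.679
pilot078,pilot,72.093,31.805,34.287,40.435,68.856
pilot079,pilot,38.744,20.074,86.917,58.437,11.284
pilot080,pilot,26.127,108.371,33.586,72.653,46.909
pilot081,pilot,52.941,48.947,62.011,67.504,44.99
pilot082,pilot,11.694,40.498,19.825,61.112,51.76
pilot083,pilot,23.575,53.505,28.825,24.184,71.254
pilot084,pilot,55.088,44.422,48.082,16.513,45.897
pilot085,pilot,78.047,60.096,84.454,61.277,39.33
pilot086,pilot,52.408,41.306,61.083,57.978,43.7
pilot087,pilot,44.062,52.249,49.608,38.655,59.927
pilot088,pilot,46.23,26.68,21.3,77.392,32.292
pilot089,pilot,64.363,78.13,56.343,45.439,37.639
pilot090,pilot,42.87,30.182,49.366,23.752,55.969
pilot091,pilot,36.175,35.184,33.617,77.788,70.077
pilot092,pilot,12.702,68.459,55.154,59.586,66.584
pilot093,pilot,60.329,73.322,53.217,54.612,44.195
pilot094,pilot,46.829,59.344,55.993,34.883,89.416
pilot095,pilot,42.034,54.365,54.514,43.216,69.148
pilot096,pilot,51.451,34.763,44.238,70.233,29.081
pilot097,pilot,46.215,23.275,59.431,51.549,36.973
pilot098,pilot,93.584,68.757,18.194,60.438,32.406
pilot099,pilot,56.055,62.756,41.577,42.55,21.066
pilot100,pilot,60.771,50.237,58.643,56.306,59.713
pilot101,pilot,32.495,42.979,18.558,44.095,72.972
pilot102,pilot,50.786,73.858,71.641,42.366,48.604
pilot103,pilot,33.94,31.416,15.38,47.225,50.901
pilot104,pilot,16.013,24.879,52.658,48.276,63.211
pilot105,pilot,51.686,75.411,24.871,55.976,50.506
pilot106,pilot,60.312,29.48,53.498,18.506,52.348
pilot107,pilot,28.97,24.687,34.455,34.674,59.802
pilot108,pilot,53.915,45.65,88.427,46.718,54.532
pilot109,pilot,59.26,39.442,58.466,55.269,28.373
pilot110,pilot,28.877,25.45,48.348,23.805,40.644
pilot111,pilot,92.085,52.853,33.516,22.405,33.917
pilot112,pilot,33.917,51.61,61.141,34.198,16.636
pilot113,pilot,69.855,38.908,70.848,62.691,45.79
pilot114,pilot,56.253,70.551,47.258,19.321,40.558
pilot115,pilot,41.922,69.871,26.388,25.093,14.863
pilot116,pilot,39.953,86.94,54.36,24.664,63.729
pilot117,pilot,8.391,93.436,4.952,36.269,7.609
pilot118,pilot,58.585,39.292,59.868,36.418,48.743
pilot119,pilot,51.463,49.281,59.845,44.287,63.653
pilot120,pilot,54.026,44.814,15.347,38.288,44.256
pilot121,pilot,46.921,76.652,64.805,50.035,51.734
pilot122,pilot,79.713,60.769,37.539,75.211,36.394
pilot123,pilot,74.568,56.679,49.189,76.855,52.649
pilot124,pilot,77.396,30.983,34.515,39.287,27.435
pilot125,pilot,50.589,65.265,53.136,52.03,50.672
pilot126,pilot,84.105,34.919,40.075,8.506,58.394
pilot127,pilot,28.847,66.643,5.13,40.949,82.0
pilot128,pilot,66.509,71.531,47.301,62.966,64.565
pilot129,pilot,23.053,10.233,29.006,32.914,4.733
pilot130,pilot,81.491,86.036,54.831,32.871,14.148
pilot131,pilot,35.9,34.171,21.604,38.124,34.249
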