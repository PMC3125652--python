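case_id,group,cell_area,cell_perimeter,nuclear_area,nuclear_perimeter
L01,leukoplakia,128.92,51.056,64.651,35.488
L02,leukoplakia,128.43,49.719,62.042,34.333
L03,leukoplakia,122.01,49.092,58.432,31.654
L04,leukoplakia,120.57,47.886,60.324,32.423
L05,leukoplakia,130.42,48.654,62.348,33.865
L06,leukoplakia,118.24,42.123,49.184,29.958
L07,leukoplakia,120.43,42.433,56.645,25.643
L08,leukoplakia,134.26,48.955,72.432,38.423
L09,leukoplakia,119.54,41.564,69.763,35.312
L10,leukoplakia,121.43,51.044,64.959,34.569
L11,leukoplakia,115.43,44.108,52.639,31.432
L12,leukoplakia,114.62,40.948,55.234,27.538
L13,leukoplakia,134.43,54.533,64.675,36.101
L14,leukoplakia,124.43,55.665,60.326,34.426
L15,leukoplakia,112.43,42.243,51.235,32.243
L16,leukoplakia,133.94,51.607,65.787,35.914
L17,leukoplakia,118.46,42.264,55.235,29.343
L18,leukoplakia,134.54,53.569,58.886,37.585
L19,leukoplakia,116.54,45.765,50.234,30.342
L20,leukoplakia,126.64,51.718,51.432,45.581
L21,leukoplakia,121.54,43.947,65.199,35.753
L22,leukoplakia,114.33,45.433,56.178,33.126
L23,leukoplakia,128.43,44.432,56.991,32.764
L24,leukoplakia,114.96,46.277,61.614,32.412
L25,leukoplakia,132.77,49.575,77.286,38.096
L26,leukoplakia,131.82,49.211,60.576,35.078
L27,leukoplakia,118.43,47.887,56.432,32.324
L28,leukoplakia,112.34,54.333,44.232,53.88
L29,leukoplakia,122.45,55.601,54.324,29.543
L30,leukoplakia,130.55,56.796,62.784,32.654
S01,scc,155.34,61.765,81.568,53.127
S02,scc,148.45,56.874,78.433,49.043
S03,scc,154.23,52.457,68.649,44.678
S04,scc,137.12,50.396,79.634,39.545
S05,scc,154.48,63.743,79.363,41.16
S06,scc,165.24,66.785,82.043,52.787
S07,scc,178.24,70.613,85.433,46.121
S08,scc,175.32,58.953,67.789,49.325
S09,scc,148.23,56.786,72.433,47.228
S10,scc,143.46,44.867,68.244,34.489
S11,scc,147.43,55.856,64.246,30.226
S12,scc,154.05,48.732,81.942,38.772
S13,scc,138.19,46.257,69.187,33.923
S14,scc,139.43,42.601,80.516,37.231
S15,scc,146.43,43.476,68.278,36.452
S16,scc,173.23,55.787,83.343,47.306
S17,scc,139.54,54.68,76.439,35.069
S18,scc,171.34,57.054,72.433,39.211
S19,scc,157.43,51.299,77.343,39.913
S20,scc,155.43,50.309,82.456,41.105
S21,scc,143.46,57.46,68.743,32.456
S22,scc,166.25,56.598,68.346,35.343
S23,scc,164.97,51.897,82.264,34.236
S24,scc,165.69,49.136,72.428,39.253
S25,scc,163.24,47.981,81.246,40.197
S26,scc,137.24,46.753,68.234,37.163
S27,scc,146.86,47.684,68.471,30.324
S28,scc,143.56,47.006,75.839,37.163
S29,scc,150.48,52.032,61.433,46.126
S30,scc,143.9,42.895,67.343,33.896
N01,normal,70.549,31.89,25.14,18.444
N02,normal,73.145,29.133,20.056,15.177
N03,normal,70.389,28.256,21.558,15.667
N04,normal,72.266,31.138,32.961,19.706
N05,normal,82.639,32.584,26.461,18.353
N06,normal,85.763,31.181,26.177,16.896
N07,normal,82.629,32.022,30.203,21.116
N08,normal,83.811,32.268,32.233,20.762
N09,normal,68.433,24.543,27.798,18.412
N10,normal,88.976,31.263,27.59,17.836
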