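cag	onset_years
57	20.91
56	19.25
60	13.45
56	14.75
57	17.05
51	25.24
37	70.39
55	19.73
48	37.8
60	14.25
40	60.11
43	38.0
38	53.07
47	39.37
50	25.3
39	49.16
50	32.12
58	19.33
44	29.67
50	27.86
42	56.6
48	32.29
48	36.83
59	13.67
56	22.2
57	21.44
53	23.39
38	58.09
40	54.99
45	35.54
56	19.25
41	44.37
54	22.82
48	28.36
57	20.89
59	14.07
56	22.78
45	33.82
52	21.29
51	28.72
47	29.13
52	19.82
52	25.22
54	20.85
56	21.42
53	21.62
46	40.49
58	14.23
58	13.85
36	58.15
53	20.24
51	30.18
60	13.34
41	65.95
43	53.87
41	50.6
57	21.2
49	22.28
40	61.87
47	25.74
39	44.34
48	36.63
51	27.02
38	48.97
56	14.72
39	43.94
46	35.98
38	64.95
38	52.55
36	61.86
39	53.96
51	21.96
49	30.53
56	18.48
40	59.59
53	33.25
46	30.84
42	38.37
59	10.11
50	28.04
42	39.78
59	17.62
38	53.47
58	16.33
52	26.65
57	16.08
39	51.6
50	25.61
46	33.84
57	17.94
58	21.82
40	39.96
38	70.86
37	62.17
53	17.87
44	38.46
55	20.85
45	40.15
38	49.91
44	38.72
48	30.83
42	39.71
59	19.08
51	23.67
38	56.45
49	26.78
43	49.35
54	22.07
54	15.17
40	59.85
38	75.08
47	28.43
55	17.26
42	44.76
57	21.89
54	18.47
44	44.94
44	44.72
56	16.91
59	12.07
57	15.58
41	33.87
58	14.2
55	27.49
52	25.58
48	33.43
50	31.51
51	25.92
55	20.91
51	23.97
48	29.68
56	20.26
43	36.84
48	36.55
43	34.16
59	14.11
41	57.12
46	36.92
45	30.69
37	79.05
37	58.35
46	37.36
43	43.31
42	44.42
52	25.06
60	17.5
36	61.38
44	37.7
37	84.45
45	34.47
48	34.93
41	55.26
44	47.67
51	27.11
46	36.72
37	73.17
46	38.66
37	51.76
41	47.09
37	47.45
59	14.99
60	13.0
37	66.07
36	91.49
47	36.0
40	48.94
41	38.98
43	45.49
55	18.61
49	25.66
53	26.52
57	24.9
43	40.9
60	15.09
58	15.2
60	11.45
36	57.35
40	55.23
48	30.26
52	16.82
39	53.52
59	13.1
47	33.46
49	26.86
52	23.56
40	44.91
36	80.74
45	33.1
59	17.2
46	28.4
49	21.81
39	56.47
57	16.1
48	36.65
39	44.0
60	16.25
54	20.92
54	21.11
38	49.05
54	23.25
47	30.14
38	68.45
59	17.17
38	61.83
48	27.75
55	20.9
60	13.12
59	10.56
37	59.12
42	37.66
42	41.48
39	47.72
37	57.03
52	23.91
39	55.99
48	28.3
44	44.85
46	38.61
50	23.89
37	60.11
42	46.81
44	44.31
39	57.2
52	26.3
45	31.07
54	18.22
46	36.21
54	19.51
43	35.37
36	65.58
51	27.68
50	25.53
55	17.32
48	34.71
40	64.6
41	57.55
51	22.54
40	61.52
56	22.87
36	61.89
36	66.91
53	19.36
39	58.89
55	17.44
50	26.61
55	23.67
37	56.85
44	58.4
48	35.56
50	32.73
53	18.43
43	46.14
43	46.12
43	35.96
40	49.23
47	37.88
49	19.77
49	30.45
45	32.6
48	27.06
36	66.27
59	16.98
46	35.48
48	26.33
54	20.24
58	15.52
54	15.37
55	19.17
44	49.48
47	32.4
46	34.11
46	39.3
40	60.71
53	20.99
46	33.04
40	49.55
60	15.91
52	28.6
41	80.57
60	13.67
52	19.05
47	32.64
49	30.55
45	38.73
55	14.61
55	21.19
54	26.68
52	32.34
36	56.8
39	62.03
40	58.57
44	38.69
56	17.35
40	64.52
53	22.48
38	56.88
55	16.4
50	20.92
52	27.49
46	35.95
50	27.12
51	25.64
46	35.83
43	45.49
44	37.1
44	41.52
46	32.63
47	35.94
51	32.45
43	36.13
52	25.91
45	36.77
39	40.58
45	35.95
55	18.59
39	52.04
53	22.11
46	35.92
59	14.95
45	29.47
45	37.9
60	15.02
38	57.38
39	65.1
42	61.84
58	13.85
49	39.43
47	35.18
57	19.71
58	16.16
38	52.6
56	14.03
48	25.72
57	14.75
41	56.3
44	42.98
58	17.42
44	35.61
53	22.27
50	24.94
45	35.63
38	54.15
47	27.79
54	25.49
48	34.8
36	74.79
44	36.28
56	16.24
49	22.19
45	33.24
51	23.02
50	31.62
56	16.82
54	18.22
43	47.42
38	46.62
51	26.17
38	61.15
36	85.14
47	33.56
59	18.52
56	22.4
40	46.52
44	35.55
43	39.13
54	17.91
55	25.72
50	23.31
55	17.39
40	53.23
50	26.96
53	17.72
49	34.13
57	17.71
38	53.64
52	24.2
40	45.78
39	48.14
41	53.37
38	65.01
40	58.71
38	52.38
36	51.26
57	14.25
54	20.58
44	53.29
55	21.69
36	85.41
41	46.88
59	14.86
43	49.31
49	27.91
58	14.17
59	13.92
50	21.17
37	60.05
36	75.39
41	48.31
48	28.66
43	37.91
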