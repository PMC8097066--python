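# published worked-example transition matrix, N=10, 3-decimal entries, transcribed verbatim
# columns are source classes, rows destinations; for structural regression only:
# the printed entries are not reproducible from the stated Gauss construction rules
0.318,0,0,0,0,0,0,0,0,0,0
0.036,0.352,0,0,0,0,0,0,0,0,0
0.066,0.036,0.352,0,0,0,0,0,0,0,0
0.114,0.066,0.036,0.352,0,0,0,0,0,0,0
0.170,0.114,0.066,0.036,0.357,0,0,0,0,0,0
0.176,0.170,0.114,0.066,0.036,0.437,0,0,0,0,0
0.080,0.176,0.170,0.114,0.066,0.036,0.613,0,0,0,0
0.005,0.080,0.176,0.170,0.114,0.066,0.036,0.783,0,0,0
0.000,0.005,0.080,0.176,0.170,0.114,0.066,0.036,0.898,0,0
0.000,0.000,0.005,0.080,0.176,0.170,0.114,0.066,0.036,0.964,0
0.000,0.000,0.000,0.005,0.080,0.176,0.170,0.114,0.066,0.036,1
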