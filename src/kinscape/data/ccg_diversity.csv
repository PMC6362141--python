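# Coastal California gnatcatcher: per-aggregation genetic diversity indices
# and percent suitable habitat within a 30-km buffer of each aggregation's
# mean center (ocean excluded). distinct=1 marks aggregations with
# significantly different allele frequencies under pairwise exact tests.
# Note: the Southwestern Riverside row is typographically ambiguous in the
# source document; the transcription below (r=0.010, Ar=5, pct=10.82) is the
# only reading consistent with the digit stream and is recorded as such.
idx,aggregation,distinct,n,ho,he,f,r,ar,pct_suitable_30km
1,Ventura,1,10,0.747,0.684,-0.101,0.153,4.13,9.15
2,Palos Verdes,1,5,0.705,0.655,-0.089,0.130,4.05,2.94
3,Coyote Hills,1,10,0.768,0.713,-0.076,0.081,4.50,9.04
4,San Dimas - Chino Hills,1,22,0.686,0.722,0.043,0.078,4.60,6.93
5,Redlands,0,5,0.653,0.654,-0.006,0.078,4.37,4.37
6,Northwestern Riverside,0,11,0.733,0.750,-0.023,0.034,4.73,11.43
7,Southwestern Riverside,0,12,0.784,0.759,-0.034,0.010,5.00,10.82
8,Santa Ana Mountains,0,27,0.733,0.743,0.020,0.049,4.79,19.43
9,San Joaquin Hills,1,36,0.751,0.758,0.008,0.033,4.70,22.67
10,South Camp Pendleton,0,35,0.746,0.779,0.047,-0.006,4.97,32.00
11,Northwest San Diego,0,11,0.766,0.764,-0.005,-0.006,4.86,21.32
12,San Pasqual,0,10,0.692,0.733,0.073,0.031,4.71,10.32
13,Cardiff - Los Penasquitos,0,16,0.712,0.742,0.033,0.039,4.89,14.04
14,Mission Trails,0,6,0.596,0.681,0.129,0.061,4.52,16.07
15,Lakeside,0,6,0.733,0.720,-0.034,0.018,4.66,12.46
16,San Diego City,0,8,0.731,0.741,0.012,0.014,4.81,18.00
17,Sweetwater,0,16,0.742,0.758,0.020,0.022,4.95,13.59
18,Otay - Jamul,0,22,0.733,0.771,0.050,0.002,5.02,15.99
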