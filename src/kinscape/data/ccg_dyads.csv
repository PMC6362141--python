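# Coastal California gnatcatcher: 34 supported first-order relative dyads
# (pairwise support P > 0.90, recovered in all replicate sibship runs).
# euclid_m / lcp_m are Euclidean and least-cost-path distances in meters
# between capture locations; regions are the sampling aggregations.
# Transcription checked against the published summary statistics
# (Euclidean mean 29943, median 4963, min 91, max 133332;
#  LCP mean 44785, median 6832, max 213881; 13 cross-aggregation pairs).
pair,prob,euclid_m,lcp_m,id1,region1,id2,region2
1,0.972,66411,93387,230059903,Redlands,268015424,San Joaquin Hills
2,1,309,309,230059911,San Pasqual,230059913,San Pasqual
3,1,357,357,230059912,San Pasqual,230059910,San Pasqual
4,1,9541,10806,230059930,Lakeside,267026817,Mission Trails
5,1,3399,3673,230059931,Lakeside,230059933,Lakeside
6,0.994,917,917,233051492,San Dimas - Chino Hills,267017523,San Dimas - Chino Hills
7,0.922,35978,57491,233051494,San Dimas - Chino Hills,267026857,Santa Ana Mountains
8,1,316,316,233051497,San Dimas - Chino Hills,233051499,San Dimas - Chino Hills
9,1,4525,5220,267017516,Ventura,267017518,Ventura
10,1,5400,8443,267017520,Ventura,267017521,Ventura
11,1,133332,195261,267017527,Otay - Jamul,268015427,Northwestern Riverside
12,0.984,117179,213881,267017529,Otay - Jamul,267026851,Southwestern Riverside
13,1,596,596,267017531,San Joaquin Hills,267017535,San Joaquin Hills
14,1,596,596,267017532,San Joaquin Hills,267017535,San Joaquin Hills
15,1,7769,9043,268016144,San Joaquin Hills,267017536,San Joaquin Hills
16,1,25519,30316,267017539,San Joaquin Hills,268016129,San Joaquin Hills
17,0.99,29401,45545,267017543,Northwest San Diego,267026831,Mission Trails
18,0.998,59704,81908,267017544,Northwest San Diego,267026865,Otay - Jamul
19,1,2459,3259,267017670,Palos Verdes,267026809,Palos Verdes
20,1,685,685,267017672,Sweetwater,267017674,Sweetwater
21,1,1163,1163,267017672,Sweetwater,267017675,Sweetwater
22,1,526,526,267017674,Sweetwater,267017675,Sweetwater
23,0.914,93004,148162,267017677,Otay - Jamul,268016106,South Camp Pendleton
24,0.995,53046,84701,267026807,San Dimas - Chino Hills,268016164,Santa Ana Mountains
25,0.977,64453,121612,267026854,Southwestern Riverside,268016143,San Joaquin Hills
26,1,19162,23187,267026863,Cardiff - Los Penasquitos,230059911,San Pasqual
27,0.967,113809,155613,268015401,Sweetwater,268015425,San Joaquin Hills
28,0.961,132113,184969,268015414,Sweetwater,268016152,Santa Ana Mountains
29,0.999,26042,27902,268016105,South Camp Pendleton,268016124,South Camp Pendleton
30,1,2401,2809,268016112,South Camp Pendleton,268016118,South Camp Pendleton
31,1,3614,5158,268016128,San Joaquin Hills,267017536,San Joaquin Hills
32,1,4125,4682,268016130,San Joaquin Hills,268016131,San Joaquin Hills
33,1,118,118,268016157,Coyote Hills,268016158,Coyote Hills
34,1,91,91,268016159,Coyote Hills,268016158,Coyote Hills
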