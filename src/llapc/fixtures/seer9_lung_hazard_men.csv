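sex,area,category,age_index,age_midpoint,hazard,se
men,san_francisco_oakland,0,8,37.5,5.11,0.5
men,san_francisco_oakland,0,9,42.5,14.34,0.92
men,san_francisco_oakland,0,10,47.5,28.9,1.39
men,san_francisco_oakland,0,11,52.5,56.89,2.11
men,san_francisco_oakland,0,12,57.5,99.87,3.1
men,san_francisco_oakland,0,13,62.5,158.96,4.4
men,san_francisco_oakland,0,14,67.5,218.55,5.68
men,san_francisco_oakland,0,15,72.5,253.56,6.6
men,san_francisco_oakland,0,16,77.5,283.49,7.95
men,san_francisco_oakland,0,17,82.5,245.25,9.08
men,san_francisco_oakland,0,18,87.5,171.04,8.72
men,connecticut,1,8,37.5,6.72,0.62
men,connecticut,1,9,42.5,16.58,1.02
men,connecticut,1,10,47.5,39.1,1.69
men,connecticut,1,11,52.5,70.97,2.38
men,connecticut,1,12,57.5,129.2,3.51
men,connecticut,1,13,62.5,203.6,4.82
men,connecticut,1,14,67.5,285.37,6.21
men,connecticut,1,15,72.5,341.7,7.29
men,connecticut,1,16,77.5,381.33,8.65
men,connecticut,1,17,82.5,325.4,9.96
men,connecticut,1,18,87.5,226.73,9.62
men,detroit,2,8,37.5,7.35,0.64
men,detroit,2,9,42.5,19.43,1.12
men,detroit,2,10,47.5,44.07,1.79
men,detroit,2,11,52.5,93.04,2.82
men,detroit,2,12,57.5,154.19,3.91
men,detroit,2,13,62.5,246.4,5.47
men,detroit,2,14,67.5,340.1,7.06
men,detroit,2,15,72.5,402.29,8.25
men,detroit,2,16,77.5,399.53,9.14
men,detroit,2,17,82.5,354.44,11.19
men,detroit,2,18,87.5,236.97,10.93
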