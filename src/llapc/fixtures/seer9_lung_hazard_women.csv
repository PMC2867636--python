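sex,area,category,age_index,age_midpoint,hazard,se
women,san_francisco_oakland,0,8,37.5,8.55,0.92
women,san_francisco_oakland,0,9,42.5,15.9,1.25
women,san_francisco_oakland,0,10,47.5,37.96,2.09
women,san_francisco_oakland,0,11,52.5,64.57,2.79
women,san_francisco_oakland,0,12,57.5,99.84,3.61
women,san_francisco_oakland,0,13,62.5,138.6,4.42
women,san_francisco_oakland,0,14,67.5,171.63,5.04
women,san_francisco_oakland,0,15,72.5,201.87,5.68
women,san_francisco_oakland,0,16,77.5,198.99,5.93
women,san_francisco_oakland,0,17,82.5,158.51,6.27
women,san_francisco_oakland,0,18,87.5,89.46,4.77
women,connecticut,1,8,37.5,11.65,1.18
women,connecticut,1,9,42.5,28.08,1.89
women,connecticut,1,10,47.5,50.51,2.59
women,connecticut,1,11,52.5,85.15,3.39
women,connecticut,1,12,57.5,124.95,4.14
women,connecticut,1,13,62.5,165.12,4.79
women,connecticut,1,14,67.5,214.92,5.58
women,connecticut,1,15,72.5,239.67,5.9
women,connecticut,1,16,77.5,241.9,6.2
women,connecticut,1,17,82.5,192.88,6.75
women,connecticut,1,18,87.5,96.76,4.74
women,detroit,2,8,37.5,10.63,1.09
women,detroit,2,9,42.5,27.29,1.81
women,detroit,2,10,47.5,58.29,2.79
women,detroit,2,11,52.5,89.58,3.44
women,detroit,2,12,57.5,141.42,4.47
women,detroit,2,13,62.5,184.48,5.18
women,detroit,2,14,67.5,242.01,6.1
women,detroit,2,15,72.5,252.02,6.19
women,detroit,2,16,77.5,245.54,6.5
women,detroit,2,17,82.5,197.33,7.22
women,detroit,2,18,87.5,99.12,5.41
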