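sex,ga_week,weight_p10_g,weight_median_g,weight_sd_g,hc_p3_cm,hc_median_cm,hc_sd_cm
male,24,558.8,660.0,79.0,20.53,22.2,0.89
male,25,643.4,760.0,91.0,21.45,23.2,0.93
male,26,736.7,870.0,104.0,22.38,24.2,0.97
male,27,837.5,990.0,119.0,23.22,25.1,1.0
male,28,948.3,1120.0,134.0,24.04,26.0,1.04
male,29,1066.5,1260.0,151.0,24.79,26.8,1.07
male,30,1193.4,1410.0,169.0,25.53,27.6,1.1
male,31,1329.1,1570.0,188.0,26.26,28.4,1.14
male,32,1472.1,1740.0,209.0,27.0,29.2,1.17
male,33,1625.2,1920.0,230.0,27.74,30.0,1.2
male,34,1785.8,2110.0,253.0,28.39,30.7,1.23
male,35,1955.0,2310.0,277.0,29.03,31.4,1.26
male,36,2133.0,2520.0,302.0,29.69,32.1,1.28
male,37,2309.6,2730.0,328.0,30.24,32.7,1.31
male,38,2478.9,2930.0,352.0,30.8,33.3,1.33
male,39,2632.0,3110.0,373.0,31.26,33.8,1.35
male,40,2767.6,3270.0,392.0,31.72,34.3,1.37
male,41,2877.1,3400.0,408.0,32.09,34.7,1.39
male,42,2961.7,3500.0,420.0,32.37,35.0,1.4
female,24,536.6,634.0,76.0,20.16,21.8,0.87
female,25,617.2,730.0,88.0,21.09,22.8,0.91
female,26,706.8,835.0,100.0,22.01,23.8,0.95
female,27,803.9,950.0,114.0,22.84,24.7,0.99
female,28,909.7,1075.0,129.0,23.68,25.6,1.02
female,29,1024.2,1210.0,145.0,24.41,26.4,1.06
female,30,1146.4,1354.0,162.0,25.15,27.2,1.09
female,31,1275.0,1507.0,181.0,25.89,28.0,1.12
female,32,1413.7,1670.0,200.0,26.64,28.8,1.15
female,33,1559.8,1843.0,221.0,27.38,29.6,1.18
female,34,1714.6,2026.0,243.0,28.02,30.3,1.21
female,35,1877.1,2218.0,266.0,28.67,31.0,1.24
female,36,2047.3,2419.0,290.0,29.31,31.7,1.27
female,37,2217.3,2621.0,315.0,29.87,32.3,1.29
female,38,2379.8,2813.0,338.0,30.42,32.9,1.32
female,39,2527.2,2986.0,358.0,30.88,33.4,1.34
female,40,2655.8,3139.0,377.0,31.34,33.9,1.36
female,41,2761.6,3264.0,392.0,31.72,34.3,1.37
female,42,2843.5,3360.0,403.0,32.0,34.6,1.38
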