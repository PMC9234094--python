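sites:
- site_id: st_josephs
  facility_level: secondary
  annual_births: 1632
  stillbirth_prob: 0.019608
  preterm_prob: 0.066875
  neonatal_death_prob: 0.019375
  infection_prob: 0.053125
  infection_subtype_mix:
  - 0.870588
  - 0.0
  - 0.129412
  microcephaly_excess_prob: 0.002
  ascertainment_sensitivity:
    low_birthweight: 0.9508
    preterm: 1.0
    sga: 0.1487
    microcephaly: 0.0124
- site_id: ejisu
  facility_level: secondary
  annual_births: 1441
  stillbirth_prob: 0.010409
  preterm_prob: 0.031557
  neonatal_death_prob: 0.0
  infection_prob: 0.016129
  infection_subtype_mix:
  - 1.0
  - 0.0
  - 0.0
  microcephaly_excess_prob: 0.002
  ascertainment_sensitivity:
    low_birthweight: 0.9394
    preterm: 0.9286
    sga: 0.1447
    microcephaly: 0.0
- site_id: tema
  facility_level: secondary
  annual_births: 5523
  stillbirth_prob: 0.038023
  preterm_prob: 0.116883
  neonatal_death_prob: 0.012046
  infection_prob: 0.013552
  infection_subtype_mix:
  - 0.888889
  - 0.027778
  - 0.083333
  microcephaly_excess_prob: 0.002
  ascertainment_sensitivity:
    low_birthweight: 0.825
    preterm: 0.9087
    sga: 0.316
    microcephaly: 0.0065
- site_id: eastern_rh
  facility_level: secondary
  annual_births: 5386
  stillbirth_prob: 0.027479
  preterm_prob: 0.135548
  neonatal_death_prob: 0.019664
  infection_prob: 0.009927
  infection_subtype_mix:
  - 0.942308
  - 0.057692
  - -0.0
  microcephaly_excess_prob: 0.002
  ascertainment_sensitivity:
    low_birthweight: 0.9856
    preterm: 0.9714
    sga: 0.2762
    microcephaly: 0.0143
- site_id: mbeya_zrh
  facility_level: tertiary
  annual_births: 7021
  stillbirth_prob: 0.023643
  preterm_prob: 0.074106
  neonatal_death_prob: 0.018089
  infection_prob: 0.010357
  infection_subtype_mix:
  - 0.943662
  - 0.028169
  - 0.028169
  microcephaly_excess_prob: 0.002
  ascertainment_sensitivity:
    low_birthweight: 0.956
    preterm: 0.8584
    sga: 0.2552
- site_id: st_francis_rh
  facility_level: tertiary
  annual_births: 3484
  stillbirth_prob: 0.03186
  preterm_prob: 0.109102
  neonatal_death_prob: 0.02105
  infection_prob: 0.021939
  infection_subtype_mix:
  - 0.891892
  - 0.054054
  - 0.054054
  microcephaly_excess_prob: 0.002
  ascertainment_sensitivity:
    low_birthweight: 0.9615
    preterm: 0.9675
    sga: 0.0
- site_id: mbeya_rrh
  facility_level: tertiary
  annual_births: 3930
  stillbirth_prob: 0.023664
  preterm_prob: 0.057858
  neonatal_death_prob: 0.015898
  infection_prob: 0.02528
  infection_subtype_mix:
  - 0.958763
  - 0.020619
  - 0.020618
  microcephaly_excess_prob: 0.002
  ascertainment_sensitivity:
    low_birthweight: 0.9859
    preterm: 0.6533
    sga: 0.5811
    microcephaly: 0.0
- site_id: mbare_pc
  facility_level: primary
  annual_births: 5500
  stillbirth_prob: 0.004909
  preterm_prob: 0.021378
  neonatal_death_prob: 0.00201
  infection_prob: 0.001827
  infection_subtype_mix:
  - 0.9
  - 0.0
  - 0.1
  microcephaly_excess_prob: 0.002
  ascertainment_sensitivity:
    low_birthweight: 0.9615
    preterm: 0.5176
    sga: 0.1584
    microcephaly: 0.0
- site_id: mutare_ph
  facility_level: tertiary
  annual_births: 1558
  stillbirth_prob: 0.057125
  preterm_prob: 0.276378
  neonatal_death_prob: 0.059905
  infection_prob: 0.004765
  infection_subtype_mix:
  - 0.857143
  - 0.0
  - 0.142857
  microcephaly_excess_prob: 0.002
  ascertainment_sensitivity:
    low_birthweight: 0.9651
    preterm: 0.9262
    sga: 0.5054
    microcephaly: 0.0
- site_id: mahdieh
  facility_level: tertiary
  annual_births: 5802
  stillbirth_prob: 0.015857
  preterm_prob: 0.20613
  neonatal_death_prob: 0.012609
  infection_prob: 0.011208
  infection_subtype_mix:
  - 0.8125
  - 0.0
  - 0.1875
  microcephaly_excess_prob: 0.002
  ascertainment_sensitivity:
    low_birthweight: 0.9877
    preterm: 0.9785
    sga: 0.8344
    microcephaly: 0.5185
- site_id: shohada_th
  facility_level: tertiary
  annual_births: 862
  stillbirth_prob: 0.030162
  preterm_prob: 0.135167
  neonatal_death_prob: 0.019139
  infection_prob: 0.072967
  infection_subtype_mix:
  - 0.868852
  - 0.016393
  - 0.114755
  microcephaly_excess_prob: 0.002
  ascertainment_sensitivity:
    low_birthweight: 0.5806
    preterm: 0.9231
    sga: 0.2143
    microcephaly: 0.1111
- site_id: castellon_guh
  facility_level: tertiary
  annual_births: 1390
  stillbirth_prob: 0.000719
  preterm_prob: 0.098632
  neonatal_death_prob: 0.00216
  infection_prob: 0.006479
  infection_subtype_mix:
  - 0.777778
  - 0.111111
  - 0.111111
  microcephaly_excess_prob: 0.002
- site_id: dr_peset_uh
  facility_level: secondary
  annual_births: 1078
  stillbirth_prob: 0.0
  preterm_prob: 0.051948
  neonatal_death_prob: 0.0
  infection_prob: 0.006494
  infection_subtype_mix:
  - 1.0
  - 0.0
  - 0.0
  microcephaly_excess_prob: 0.002
- site_id: jss
  facility_level: tertiary
  annual_births: 2786
  stillbirth_prob: 0.009332
  preterm_prob: 0.139855
  neonatal_death_prob: 0.006159
  infection_prob: 0.022464
  infection_subtype_mix:
  - 0.887097
  - 0.032258
  - 0.080645
  microcephaly_excess_prob: 0.002
  ascertainment_sensitivity:
    low_birthweight: 0.9648
    preterm: 0.9297
    sga: 0.2748
    microcephaly: 0.0095
- site_id: grant_gmc
  facility_level: tertiary
  annual_births: 2247
  stillbirth_prob: 0.042724
  preterm_prob: 0.177592
  neonatal_death_prob: 0.036262
  infection_prob: 0.007903
  infection_subtype_mix:
  - 0.823529
  - 0.117647
  - 0.058824
  microcephaly_excess_prob: 0.002
  ascertainment_sensitivity:
    low_birthweight: 0.975
    preterm: 0.9888
    sga: 0.0574
- site_id: ims_sum
  facility_level: tertiary
  annual_births: 1805
  stillbirth_prob: 0.039335
  preterm_prob: 0.213379
  neonatal_death_prob: 0.004037
  infection_prob: 0.015571
  infection_subtype_mix:
  - 0.888889
  - 0.111111
  - -0.0
  microcephaly_excess_prob: 0.002
  ascertainment_sensitivity:
    low_birthweight: 1.0
    preterm: 1.0
    sga: 0.3333
    microcephaly: 0.5
- site_id: kasturba_mc
  facility_level: tertiary
  annual_births: 2762
  stillbirth_prob: 0.014844
  preterm_prob: 0.24513
  neonatal_death_prob: 0.011025
  infection_prob: 0.027931
  infection_subtype_mix:
  - 0.934211
  - 0.039474
  - 0.026315
  microcephaly_excess_prob: 0.002
  ascertainment_sensitivity:
    low_birthweight: 0.9962
    preterm: 0.9781
    sga: 0.4062
    microcephaly: 0.0
- site_id: mp_shah_mc
  facility_level: tertiary
  annual_births: 9971
  stillbirth_prob: 0.016347
  preterm_prob: 0.084625
  neonatal_death_prob: 0.006321
  infection_prob: 0.008972
  infection_subtype_mix:
  - 0.806818
  - 0.011364
  - 0.181818
  microcephaly_excess_prob: 0.002
  ascertainment_sensitivity:
    low_birthweight: 0.9469
    preterm: 0.8656
    sga: 0.0742
    microcephaly: 0.0103
- site_id: skims
  facility_level: tertiary
  annual_births: 3184
  stillbirth_prob: 0.015075
  preterm_prob: 0.120855
  neonatal_death_prob: 0.010204
  infection_prob: 0.010842
  infection_subtype_mix:
  - 1.0
  - 0.0
  - 0.0
  microcephaly_excess_prob: 0.002
- site_id: patan
  facility_level: tertiary
  annual_births: 7555
  stillbirth_prob: 0.011516
  preterm_prob: 0.118773
  neonatal_death_prob: 0.005624
  infection_prob: 0.037761
  infection_subtype_mix:
  - 0.397163
  - 0.180851
  - 0.421986
  microcephaly_excess_prob: 0.002
- site_id: bp_koirala
  facility_level: tertiary
  annual_births: 10554
  stillbirth_prob: 0.02094
  preterm_prob: 0.056131
  neonatal_death_prob: 0.00271
  infection_prob: 0.013646
  infection_subtype_mix:
  - 0.524823
  - 0.170213
  - 0.304964
  microcephaly_excess_prob: 0.002
windows:
  eastern_rh: 19
  ejisu: 18
  grant_gmc: 7
  ims_sum: 17
  jss: 19
  kasturba_mc: 25
  mahdieh: 24
  mbare_pc: 22
  mbeya_rrh: 16
  mbeya_zrh: 16
  mp_shah_mc: 27
  mutare_ph: 21
  shohada_th: 30
  st_francis_rh: 16
  st_josephs: 18
  tema: 19
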