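site_id,weeks,outcome,n_total,n_site
st_josephs,18,low_birthweight,61,58
st_josephs,18,preterm,28,28
st_josephs,18,sga,195,29
st_josephs,18,microcephaly,161,2
ejisu,18,low_birthweight,33,31
ejisu,18,preterm,14,13
ejisu,18,sga,76,11
ejisu,18,microcephaly,36,0
tema,19,low_birthweight,200,165
tema,19,preterm,241,219
tema,19,sga,231,73
tema,19,microcephaly,153,1
eastern_rh,19,low_birthweight,277,273
eastern_rh,19,preterm,280,272
eastern_rh,19,sga,315,87
eastern_rh,19,microcephaly,70,1
mbeya_zrh,16,low_birthweight,159,152
mbeya_zrh,16,preterm,226,194
mbeya_zrh,16,sga,192,49
mbeya_zrh,16,microcephaly,0,0
st_francis_rh,16,low_birthweight,104,100
st_francis_rh,16,preterm,123,119
st_francis_rh,16,sga,128,0
st_francis_rh,16,microcephaly,0,0
mbeya_rrh,16,low_birthweight,71,70
mbeya_rrh,16,preterm,75,49
mbeya_rrh,16,sga,74,43
mbeya_rrh,16,microcephaly,22,0
mbare_pc,22,low_birthweight,78,75
mbare_pc,22,preterm,85,44
mbare_pc,22,sga,202,32
mbare_pc,22,microcephaly,9,0
mutare_ph,21,low_birthweight,172,166
mutare_ph,21,preterm,149,138
mutare_ph,21,sga,93,47
mutare_ph,21,microcephaly,9,0
mahdieh,24,low_birthweight,325,321
mahdieh,24,preterm,372,364
mahdieh,24,sga,151,126
mahdieh,24,microcephaly,54,28
shohada_th,30,low_birthweight,31,18
shohada_th,30,preterm,39,36
shohada_th,30,sga,14,3
shohada_th,30,microcephaly,9,1
jss,19,low_birthweight,142,137
jss,19,preterm,128,119
jss,19,sga,131,36
jss,19,microcephaly,210,2
grant_gmc,7,low_birthweight,120,117
grant_gmc,7,preterm,89,88
grant_gmc,7,sga,122,7
grant_gmc,7,microcephaly,0,0
ims_sum,17,low_birthweight,85,85
ims_sum,17,preterm,79,79
ims_sum,17,sga,75,25
ims_sum,17,microcephaly,2,1
kasturba_mc,25,low_birthweight,264,263
kasturba_mc,25,preterm,228,223
kasturba_mc,25,sga,160,65
kasturba_mc,25,microcephaly,22,0
mp_shah_mc,27,low_birthweight,923,874
mp_shah_mc,27,preterm,387,335
mp_shah_mc,27,sga,741,55
mp_shah_mc,27,microcephaly,292,3
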