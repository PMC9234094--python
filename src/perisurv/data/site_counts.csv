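site_id,site_name,country,facility_level,total_births,livebirths,stillbirth,neonatal_death,low_birthweight,preterm,sga,microcephaly,neonatal_infection,infection_bloodstream,infection_meningitis,infection_respiratory
st_josephs,St Joseph's H,Ghana,secondary,1632,1600,32,31,220,107,105,2,85,74,0,11
ejisu,Ejisu H,Ghana,secondary,1441,1426,15,0,89,45,25,2,23,23,0,0
tema,Tema GH,Ghana,secondary,5523,5313,210,64,554,621,341,5,72,64,2,6
eastern_rh,Eastern RH,Ghana,secondary,5386,5238,148,103,753,710,247,2,52,49,3,0
mbeya_zrh,Mbeya ZRH,Tanzania,tertiary,7021,6855,166,124,682,508,116,1,71,67,2,2
st_francis_rh,St Francis RH,Tanzania,tertiary,3484,3373,111,71,431,368,,,74,66,4,4
mbeya_rrh,Mbeya RRH,Tanzania,tertiary,3930,3837,93,61,321,222,119,3,97,93,2,2
mbare_pc,Mbare PC,Zimbabwe,primary,5500,5473,27,11,237,117,131,0,10,9,0,1
mutare_ph,Mutare PH,Zimbabwe,tertiary,1558,1469,89,88,484,406,119,0,7,6,0,1
mahdieh,Mahdieh H,Iran,tertiary,5802,5710,92,72,970,1177,249,30,64,52,0,12
shohada_th,Shohada TH,Iran,tertiary,862,836,26,16,82,113,17,8,61,53,1,7
castellon_guh,Castellon GUH,Spain,tertiary,1390,1389,1,3,158,137,85,18,9,7,1,1
dr_peset_uh,Dr Peset UH,Spain,secondary,1078,1078,0,0,56,56,60,14,7,7,0,0
jss,JSS H,India,tertiary,2786,2760,26,17,487,386,124,9,62,55,2,5
grant_gmc,Grant GMC,India,tertiary,2247,2151,96,78,491,382,45,0,17,14,2,1
ims_sum,IMS SUM H,India,tertiary,1805,1734,71,7,445,370,109,6,27,24,3,0
kasturba_mc,Kasturba MC,India,tertiary,2762,2721,41,30,708,667,172,11,76,71,3,2
mp_shah_mc,MP Shah MC,India,tertiary,9971,9808,163,62,2421,830,181,9,88,71,1,16
skims,SKIMS,India,tertiary,3184,3136,48,32,299,379,37,1,34,34,0,0
patan,Patan H,Nepal,tertiary,7555,7468,87,42,1064,887,126,3,282,112,51,119
bp_koirala,BP Koirala,Nepal,tertiary,10554,10333,221,28,1327,580,818,15,141,74,24,43
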