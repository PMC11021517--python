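# Surgical cohort: 22 patients, ILAE seizure outcome and detector event
# rates (events/min) in the pre- and post-resection ECoG. Rates the
# source reports only as "<1" are stored as 0.5 (any value below the
# 1/min decision threshold is equivalent for classification).
# electrodes: hd = high-density grid (5 mm spacing), std = standard (10 mm).
patient_id,ilae,electrodes,hfo_pre_rate,hfo_post_rate,iedhfo_post_rate
USZ1,1,hd,6,0.5,0.5
USZ2,1,hd,5,0.5,0.5
USZ3,1,hd,1,0.5,0.5
USZ4,1,hd,2,0.5,0.5
USZ5,1,hd,4,0.5,0.5
USZ6,3,hd,10,1,1
USZ7,1,hd,2,0.5,0.5
USZ8,1,hd,30,0.5,0.5
USZ9,1,std,0.5,0.5,0.5
USZ10,3,std,0.5,0.5,0.5
USZ11,1,std,2,0.5,0.5
USZ12,1,std,0.5,0.5,0.5
USZ13,5,std,5,0.5,0.5
USZ14,1,std,5,0.5,0.5
USZ15,5,std,0.5,0.5,0.5
USZ16,1,std,0.5,0.5,0.5
USZ17,3,std,0.5,0.5,0.5
USZ18,5,std,7,6,6
USZ19,5,std,0.5,0.5,0.5
USZ20,1,std,5,0.5,0.5
USZ21,5,std,0.5,0.5,0.5
USZ22,1,std,0.5,0.5,0.5
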