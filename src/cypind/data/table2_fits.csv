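compound,conc_low_um,conc_high_um,lot,status,r_squared,emax,ec50,max_fold_induction
rifampicin,0.01,50,2B,fit,0.98,22,0.36,
rifampicin,0.01,50,3A,fit,0.96,28,0.27,
rifampicin,0.01,50,3B,fit,0.98,26,0.52,
phenytoin,0.6,120,2B,fit,1.00,23,15,
phenytoin,0.6,120,3A,fit,1.00,38,16,
phenytoin,0.6,120,3B,fit,0.99,35,23,
carbamazepine,0.23,500,2B,fit,1.00,16,108,
carbamazepine,0.23,500,3A,fit,1.00,10,65,
carbamazepine,0.23,500,3B,fit,0.98,14,53,
phenobarbital,0.91,2000,2B,fit,1.00,110,558,
phenobarbital,0.91,2000,3A,fit,1.00,135,728,
phenobarbital,0.91,2000,3B,fit,1.00,73,775,
terbinafine,0.05,100,2B,fit,1.00,20,3.6,
terbinafine,0.05,100,3A,fit,1.00,24,2.2,
terbinafine,0.05,100,3B,fit,0.99,21,2.7,
sulfinpyrazone,0.09,200,2B,fit,1.00,31,23,
sulfinpyrazone,0.09,200,3A,fit,0.98,53,28,
sulfinpyrazone,0.09,200,3B,fit,0.98,38,32,
probenecid,0.13,300,2B,fit,1.00,25,187,
probenecid,0.13,300,3A,fit,1.00,26,176,
probenecid,0.13,300,3B,fit,1.00,22,195,
pioglitazone,0.006,12.5,2B,fit,0.99,33,3.3,
pioglitazone,0.006,12.5,3A,fit,0.99,31,2.3,
pioglitazone,0.006,12.5,3B,fit,0.98,15,2.0,
dexamethasone,0.11,250,2B,fit,1.00,32,139,
dexamethasone,0.11,250,3A,fit,1.00,53,117,
dexamethasone,0.11,250,3B,fit,1.00,29,134,
rosiglitazone,0.05,100,2B,fit,0.99,49,3.8,
rosiglitazone,0.05,100,3A,fit,1.00,85,4.3,
rosiglitazone,0.05,100,3B,fit,1.00,95,4,
omeprazole,0.05,100,2B,fit,1.00,24,13,
omeprazole,0.05,100,3A,fit,1.00,45,23,
omeprazole,0.05,100,3B,fit,1.00,27,13,
clotrimazole,0.005,10,2B,fit,1.00,16,0.58,
clotrimazole,0.005,10,3A,fit,0.99,18,0.35,
clotrimazole,0.005,10,3B,fit,1.00,17,0.33,
nifedipine,0.05,100,2B,fit,1.00,28,5.6,
nifedipine,0.05,100,3A,fit,0.99,40,6.6,
nifedipine,0.05,100,3B,fit,0.99,27,3.5,
quinidine,0.11,250,2B,na,,,,1.0
quinidine,0.11,250,3A,na,,,,2.0
quinidine,0.11,250,3B,ni,,,,1.12
flumazenil,0.023,50,2B,ni,,,,
flumazenil,0.023,50,3A,ni,,,,
flumazenil,0.023,50,3B,ni,,,,
primaquine,0.05,40,2B,ni,,,,
primaquine,0.05,40,3A,ni,,,,
primaquine,0.05,40,3B,ni,,,,
methotrexate,0.009,20,2B,ni,,,,
methotrexate,0.009,20,3A,ni,,,,
methotrexate,0.009,20,3B,ni,,,,
digoxin,0.0002,0.2,2B,ni,,,,
digoxin,0.0002,0.2,3A,ni,,,,
digoxin,0.0002,0.2,3B,ni,,,,
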