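compound,endpoint,lot,ris
rifampicin,mrna,2B,19.1
rifampicin,mrna,3A,24.8
rifampicin,mrna,3B,21.5
phenytoin,mrna,2B,7.5
phenytoin,mrna,3A,12.1
phenytoin,mrna,3B,8.5
carbamazepine,mrna,2B,0.76
carbamazepine,mrna,3A,0.77
carbamazepine,mrna,3B,1.3
phenobarbital,mrna,2B,5.2
phenobarbital,mrna,3A,5.0
phenobarbital,mrna,3B,2.5
terbinafine,mrna,2B,0.13
terbinafine,mrna,3A,0.26
terbinafine,mrna,3B,0.19
pioglitazone,mrna,2B,0.28
pioglitazone,mrna,3A,0.37
pioglitazone,mrna,3B,0.21
sulfinpyrazone,mrna,2B,1.2
sulfinpyrazone,mrna,3A,1.8
sulfinpyrazone,mrna,3B,1.1
probenecid,mrna,2B,2.8
probenecid,mrna,3A,3.2
probenecid,mrna,3B,2.4
dexamethasone,mrna,2B,0.0013
dexamethasone,mrna,3A,0.0024
dexamethasone,mrna,3B,0.0012
nifedipine,mrna,2B,0.10
nifedipine,mrna,3A,0.12
nifedipine,mrna,3B,0.16
rosiglitazone,mrna,2B,0.043
rosiglitazone,mrna,3A,0.065
rosiglitazone,mrna,3B,0.070
omeprazole,mrna,2B,0.069
omeprazole,mrna,3A,0.073
omeprazole,mrna,3B,0.079
clotrimazole,mrna,2B,0.0028
clotrimazole,mrna,3A,0.0051
clotrimazole,mrna,3B,0.0052
rifampicin,activity,2B,23.8
rifampicin,activity,3A,23.0
rifampicin,activity,3B,18.3
phenytoin,activity,2B,1.8
phenytoin,activity,3A,2.3
phenytoin,activity,3B,2.4
carbamazepine,activity,2B,0.67
carbamazepine,activity,3A,0.8
carbamazepine,activity,3B,0.9
phenobarbital,activity,2B,2.9
phenobarbital,activity,3A,4.2
phenobarbital,activity,3B,4.0
terbinafine,activity,2B,0.15
terbinafine,activity,3A,0.23
terbinafine,activity,3B,0.17
pioglitazone,activity,2B,0.12
pioglitazone,activity,3A,0.20
pioglitazone,activity,3B,0.28
sulfinpyrazone,activity,2B,1.5
sulfinpyrazone,activity,3A,1.4
sulfinpyrazone,activity,3B,1.2
probenecid,activity,2B,1.5
probenecid,activity,3A,1.0
probenecid,activity,3B,0.8
dexamethasone,activity,2B,0.00054
dexamethasone,activity,3A,0.00041
dexamethasone,activity,3B,0.00043
nifedipine,activity,2B,0.09
nifedipine,activity,3A,0.09
nifedipine,activity,3B,0.04
rosiglitazone,activity,2B,0.019
rosiglitazone,activity,3A,0.028
rosiglitazone,activity,3B,0.024
omeprazole,activity,2B,0.015
omeprazole,activity,3A,0.009
omeprazole,activity,3B,0.007
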