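compound,endpoint,lot,predicted_auc_change_pct
rifampicin,mrna,2B,98
rifampicin,mrna,3A,98
rifampicin,mrna,3B,95
rifampicin,activity,2B,96
rifampicin,activity,3A,96
rifampicin,activity,3B,99
phenytoin,mrna,2B,98
phenytoin,mrna,3A,98
phenytoin,mrna,3B,95
phenytoin,activity,2B,96
phenytoin,activity,3A,96
phenytoin,activity,3B,97
carbamazepine,mrna,2B,86
carbamazepine,mrna,3A,87
carbamazepine,mrna,3B,95
carbamazepine,activity,2B,92
carbamazepine,activity,3A,92
carbamazepine,activity,3B,87
phenobarbital,mrna,2B,98
phenobarbital,mrna,3A,98
phenobarbital,mrna,3B,95
phenobarbital,activity,2B,96
phenobarbital,activity,3A,96
phenobarbital,activity,3B,98
pioglitazone,mrna,2B,36
pioglitazone,mrna,3A,35
pioglitazone,mrna,3B,29
pioglitazone,activity,2B,17
pioglitazone,activity,3A,23
pioglitazone,activity,3B,34
terbinafine,mrna,2B,8.1
terbinafine,mrna,3A,13
terbinafine,mrna,3B,19
terbinafine,activity,2B,29
terbinafine,activity,3A,29
terbinafine,activity,3B,15
sulfinpyrazone,mrna,2B,94
sulfinpyrazone,mrna,3A,97
sulfinpyrazone,mrna,3B,95
sulfinpyrazone,activity,2B,96
sulfinpyrazone,activity,3A,95
sulfinpyrazone,activity,3B,92
probenecid,mrna,2B,98
probenecid,mrna,3A,98
probenecid,mrna,3B,95
probenecid,activity,2B,96
probenecid,activity,3A,94
probenecid,activity,3B,83
dexamethasone,mrna,2B,0.00
dexamethasone,mrna,3A,0.00
dexamethasone,mrna,3B,0.00
dexamethasone,activity,2B,0.0
dexamethasone,activity,3A,0.0
dexamethasone,activity,3B,0.0
nifedipine,mrna,2B,4.4
nifedipine,mrna,3A,0.89
nifedipine,mrna,3B,8.3
nifedipine,activity,2B,8.9
nifedipine,activity,3A,2.1
nifedipine,activity,3B,0.63
omeprazole,mrna,2B,1.7
omeprazole,mrna,3A,0.14
omeprazole,mrna,3B,0.35
omeprazole,activity,2B,0.11
omeprazole,activity,3A,0.002
omeprazole,activity,3B,0.017
rosiglitazone,mrna,2B,0.53
rosiglitazone,mrna,3A,0.10
rosiglitazone,mrna,3B,0.20
rosiglitazone,activity,2B,0.21
rosiglitazone,activity,3A,0.077
rosiglitazone,activity,3B,0.22
clotrimazole,mrna,2B,0.00
clotrimazole,mrna,3A,0.00
clotrimazole,mrna,3B,0.00
clotrimazole,activity,2B,0
clotrimazole,activity,3A,0
clotrimazole,activity,3B,0
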