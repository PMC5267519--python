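name,cmax_ub_um,observed_auc_change_pct,substrate_class,in_calibration_set,category
rifampicin,,97,midazolam,True,strong
phenytoin,,94,midazolam,True,strong
carbamazepine,,94,midazolam,True,strong
phenobarbital,,61,nonmidazolam,False,moderate_weak
pioglitazone,,26,midazolam,True,moderate_weak
terbinafine,,25,midazolam,True,moderate_weak
sulfinpyrazone,,22,nonmidazolam,False,moderate_weak
probenecid,28,20,nonmidazolam,False,moderate_weak
dexamethasone,,19,nonmidazolam,False,noninducer
nifedipine,,4,midazolam,True,noninducer
omeprazole,,-25,nonmidazolam,False,noninducer
rosiglitazone,,12,nonmidazolam,False,noninducer
clotrimazole,,9.7,nonmidazolam,False,noninducer
quinidine,,,,False,noninducer
flumazenil,,,,False,noninducer
primaquine,,,,False,noninducer
methotrexate,,,,False,noninducer
digoxin,,,,False,noninducer
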