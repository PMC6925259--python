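# Synthetic cohort annotation table for a 45-model Wilms tumor PDX library.
# Cohort-level marginals (histologic concordance 38/45; 11p15 category
# counts 17/2/18/3/5; 1q gain 13/45; combined 1p+16q LOH 1/45) are
# fixed by construction; per-model placements not pinned by named
# evidence are synthetic, as are blastema percentages and stages.
model_id,histology,stage,bilateral,neoadjuvant,relapse,primary_available,histology_concordant,discordance_reason,status_11p15,pct_blastema_primary,pct_blastema_xeno,pct_blastema_passages,TP53_xeno,TP53_primary,WT1_xeno,WT1_primary,CTNNB1_xeno,CTNNB1_primary,SIX1_2_xeno,SIX1_2_primary,DROSHA_xeno,DROSHA_primary,DGCR8_xeno,DGCR8_primary,MYCN_xeno,MYCN_primary,gain_1q_xeno,gain_1q_primary,loh_16q_xeno,loh_16q_primary,loh_1p_xeno,loh_1p_primary,loh_17p_xeno,loh_17p_primary
KT-20,favorable,3,0,0,0,1,1,,UPD,17,57,51;72;63;57;43,0,0,0,0,0,0,0,0,0,0,0,0,1,1,0,0,0,0,0,0,0,0
KT-21,favorable,2,0,0,1,1,1,,UPD,10,59,52;57;61;48;56,0,0,0,0,0,0,0,0,1,1,0,0,0,0,1,1,0,0,0,0,0,0
KT-22,favorable,5,1,1,0,1,1,,UPD,15,95,73;50;57;52;54,0,0,1,1,1,1,0,0,1,1,0,0,0,0,0,0,0,0,0,0,0,0
KT-23,diffuse_anaplasia,4,0,1,1,1,0,anaplasia_not_detected,UPD,13,95,,1,1,0,0,0,0,1,1,1,1,0,0,0,0,1,1,0,0,0,0,0,0
KT-24,favorable,4,0,0,1,1,1,,UPD,74,11,98;98;98;98;98,0,0,0,0,0,0,1,1,0,0,0,0,0,0,1,1,0,0,0,0,0,0
KT-25,favorable,5,1,1,0,1,1,,UPD,22,6,66;53;70;79;68,0,0,1,1,1,1,1,1,1,1,0,0,0,0,0,0,0,0,0,0,0,0
KT-26,favorable,2,0,1,0,1,1,,UPD,5,37,49;58;49;51;46,0,0,0,0,0,0,0,0,1,1,0,0,0,0,0,0,0,0,0,0,0,0
KT-27,favorable,5,1,1,0,1,1,,normal,59,78,,0,0,1,1,1,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
KT-28,favorable,4,0,0,1,1,1,,hemizygous_loss,68,62,,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1,1,1,1,1,1,0,0
KT-29,favorable,4,0,1,1,1,0,triphasic_to_monomorphic,UPD,66,50,,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
KT-30,favorable,5,1,1,0,1,1,,UPD,31,56,68;59;94;59;49,0,0,1,1,1,1,1,1,0,0,0,0,0,0,0,0,1,1,0,0,0,0
KT-31,favorable,5,1,0,0,0,1,,UPD,16,33,,0,,0,,0,,0,,0,,0,,0,,0,,0,,0,,0,
KT-32,favorable,5,1,0,0,0,1,,UPD,56,76,,0,,0,,0,,0,,0,,0,,0,,0,,0,,0,,0,
KT-33,favorable,5,1,1,0,1,1,,normal,48,44,,0,0,1,1,1,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
KT-34,favorable,5,1,0,0,0,1,,UPD,72,85,,0,,0,,0,,0,,0,,0,,0,,0,,0,,0,,0,
KT-35,favorable,3,0,0,0,0,1,,UPD,52,23,,0,,0,,0,,0,,0,,0,,0,,0,,0,,0,,0,
KT-36,favorable,1,0,0,0,0,1,,UPD,63,79,,0,,0,,0,,0,,0,,0,,0,,0,,0,,0,,0,
KT-37,favorable,5,1,1,0,1,1,,paternal_gain,48,34,,0,0,1,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
KT-38,favorable,3,0,0,0,0,1,,UPD,26,54,,0,,0,,0,,0,,0,,0,,0,,0,,0,,0,,0,
KT-39,favorable,1,0,0,0,1,1,,UPD,50,69,,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
KT-40,favorable,2,0,0,0,1,1,,UPD,72,85,,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
KT-41,favorable,1,0,0,0,1,1,,LOI,22,0,,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
KT-42,favorable,1,0,0,0,1,1,,LOI,68,4,,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
KT-43,favorable,2,0,1,0,1,0,triphasic_to_monomorphic,LOI,60,95,,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1,1,0,0,0,0,0,0
KT-44,favorable,3,0,0,0,1,1,,LOI,39,95,,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
KT-45,favorable,5,1,1,0,1,1,,LOI,66,87,98;98;98;98;98,0,0,0,0,0,0,0,0,0,0,1,1,0,0,0,0,0,0,0,0,0,0
KT-46,favorable,2,0,0,0,1,1,,LOI,58,72,,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
KT-47,favorable,5,1,1,0,1,1,,LOI,52,44,96;98;98;90;85,0,0,0,0,0,0,0,0,0,0,1,1,0,0,0,0,0,0,0,0,0,0
KT-48,favorable,4,0,0,0,1,1,,LOI,46,24,,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
KT-49,favorable,1,0,0,0,1,1,,LOI,38,83,,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
KT-51,diffuse_anaplasia,1,0,0,1,1,1,,paternal_gain,37,53,,1,1,0,0,0,0,0,0,0,0,0,0,0,0,1,1,0,0,0,0,1,1
KT-52,favorable,1,0,1,0,1,0,triphasic_to_monomorphic,LOI,63,95,,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
KT-53,diffuse_anaplasia,3,0,0,0,1,1,,LOI,55,82,,1,1,0,0,0,0,0,0,0,0,0,0,0,0,1,1,0,0,1,1,1,1
KT-55,favorable,2,0,1,0,1,1,,normal,52,66,,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
KT-58,favorable,3,0,1,0,1,0,triphasic_to_monomorphic,LOI,39,77,,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1,1,0,0,0,0,0,0
KT-59,favorable,5,1,1,1,1,1,,LOI,49,30,,0,0,0,0,0,0,1,1,1,1,0,0,0,0,0,0,0,0,0,0,0,0
KT-60,diffuse_anaplasia,1,0,0,0,1,1,,paternal_gain,19,71,,1,1,0,0,0,0,0,0,0,0,0,0,0,0,1,1,0,0,0,0,1,1
KT-64,favorable,3,0,0,1,1,1,,LOI,27,54,,1,1,0,0,0,0,0,0,0,0,0,0,0,0,1,1,0,0,0,0,0,0
KT-66,favorable,3,0,0,0,1,1,,LOI,29,18,,1,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
KT-67,focal_anaplasia,2,0,0,0,1,0,anaplasia_not_detected,LOI,31,95,,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
KT-69,diffuse_anaplasia,1,0,0,0,1,1,,normal,11,47,,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
KT-71,diffuse_anaplasia,1,0,0,0,1,0,anaplasia_not_detected,LOI,57,70,,1,1,0,0,0,0,0,0,0,0,0,0,0,0,1,1,0,0,0,0,1,1
KT-74,favorable,5,1,0,0,1,1,,normal,24,93,,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
KT-75,favorable,3,0,0,0,1,1,,LOI,63,95,,0,0,0,0,0,0,0,0,0,0,1,1,0,0,1,1,0,0,0,0,0,0
KT-76,favorable,1,0,1,1,1,1,,hemizygous_loss,28,74,,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1,1,0,0,0,0,0,0
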