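trial_id,form,preliminary,adjustment,final,provenance
calypso,2c,3,0,3,"Table 1, platinum-sensitive: carboplatin/PLD (CALYPSO)"
icon4,2a,4,0,4,"Table 1, platinum-sensitive: paclitaxel plus platinum (ICON4/AGO-OVAR 2.2)"
carbo_gem,2b,3,-1,2,"Table 1, platinum-sensitive: carboplatin plus gemcitabine"
carbo_pld_bev,2b,1,0,1,"Table 1, platinum-sensitive: carboplatin/PLD/bevacizumab"
mito16b,2b,3,0,3,"Table 1, platinum-sensitive: carboplatin doublet plus bevacizumab (MITO16b)"
icon6,2b,2,-1,1,"Table 1, maintenance: cediranib (ICON6, ITT unselected)"
nova,not_graded,,0,,"Table 1, maintenance: niraparib ITT row (no data printed; cohort analyses prespecified)"
nova_gbrca,2b,3,0,3,"Table 1, maintenance: niraparib, gBRCA-mutated cohort"
nova_non_gbrca,2b,3,0,3,"Table 1, maintenance: niraparib, non-gBRCA cohort (including HRD+)"
nova_hrd_pos,not_graded,,0,,"Table 1, maintenance: niraparib, HRD+ subset (exploratory, not scored)"
ariel3_itt,2b,3,0,3,"Table 1, maintenance: rucaparib ITT (ARIEL3)"
ariel3_brca,2b,3,0,3,"Table 1, maintenance: rucaparib, BRCA-mutated subgroup (ARIEL3)"
ariel3_hrd,2b,3,0,3,"Table 1, maintenance: rucaparib, HRD subgroup incl. BRCA-mutated (ARIEL3)"
solo2,2b,3,-1,2,"Table 1, maintenance: olaparib tablets ITT, all gBRCA-mutated (SOLO2)"
oceans,2b,3,-1,2,"Table 1, maintenance: bevacizumab added to carboplatin/gemcitabine (OCEANS)"
ova301,2b,3,-1,2,"Table 1, platinum-resistant: trabectedin plus PLD"
aurelia,2b,3,1,4,"Table 1, platinum-resistant: bevacizumab added to chemotherapy (AURELIA)"
trinova1,2b,3,-1,2,"Table 1, platinum-resistant: trebananib plus paclitaxel (TRINOVA-1)"
topotecan_orr,3,2,0,2,"Table 1, platinum-resistant: topotecan vs paclitaxel (graded on ORR)"
study19_itt,2b,3,-1,2,"Table 2, maintenance: olaparib capsules ITT (STUDY19)"
study19_brca_mut,2b,3,-1,2,"Table 2, maintenance: olaparib capsules, BRCA-mutated subgroup (STUDY19)"
study19_brca_wt,2b,3,-1,2,"Table 2, maintenance: olaparib capsules, BRCA-wild-type subgroup (STUDY19)"
olaparib_concomitant,2b,2,0,2,"Table 2, maintenance: olaparib concomitant with chemotherapy then maintenance"
trias,2b,3,0,3,"Table 2, platinum-resistant: sorafenib plus topotecan (TRIAS)"
berzosertib,2b,3,-1,2,"Table 2, platinum-resistant: berzosertib plus gemcitabine"
adavosertib,2a,4,0,4,"Table 2, platinum-resistant: adavosertib plus gemcitabine"
farletuzumab,not_graded,,0,,"Table 3, platinum-sensitive: farletuzumab (not significant)"
carbo_topotecan,not_graded,,0,,"Table 3, platinum-sensitive: carboplatin/topotecan (not significant)"
mito8,not_graded,,0,,"Table 3, platinum-sensitive: MITO-8 (PFS control arm significantly better)"
micellar_paclitaxel,not_graded,,0,,"Table 3, platinum-sensitive: carboplatin/paclitaxel micellar (non-inferiority; no QoL or symptom improvement, no score)"
vismodegib,not_graded,,0,,"Table 3, maintenance: vismodegib (not significant)"
gog0213,not_graded,,0,,"Table 3, maintenance: bevacizumab (GOG-0213, not significant)"
pld_vs_topotecan,not_graded,,0,,"Table 3, platinum-resistant: PLD vs topotecan (not significant)"
epidox_paclitaxel,not_graded,,0,,"Table 3, platinum-resistant: epidoxorubicin plus paclitaxel (not significant)"
pld_vs_gem,not_graded,,0,,"Table 3, platinum-resistant: PLD vs gemcitabine (not significant)"
pld_vs_gem_ttp,not_graded,,0,,"Table 3, platinum-resistant: PLD vs gemcitabine, TTP primary (not significant)"
topo_combo,not_graded,,0,,"Table 3, platinum-resistant: topotecan combinations (not significant)"
canfosfamide,not_graded,,0,,"Table 3, platinum-resistant: canfosfamide (control arm significantly better)"
pertuzumab_gem,not_graded,,0,,"Table 3, platinum-resistant: pertuzumab plus gemcitabine (not significant)"
pertuzumab_chemo,not_graded,,0,,"Table 3, platinum-resistant: pertuzumab plus carboplatin doublet (not significant)"
pacl_combo_vs_pacl,not_graded,,0,,"Table 3, platinum-resistant: paclitaxel combinations vs paclitaxel (not significant)"
olaparib_vs_pld,not_graded,,0,,"Table 3, platinum-resistant: olaparib vs PLD (not significant)"
patupilone,not_graded,,0,,"Table 3, platinum-resistant: patupilone (not significant)"
vandetanib,not_graded,,0,,"Table 3, platinum-resistant: docetaxel plus vandetanib (not significant)"
seribantumab,not_graded,,0,,"Table 3, platinum-resistant: seribantumab plus paclitaxel (not significant)"
motolimod,not_graded,,0,,"Table 3, platinum-resistant: motolimod plus PLD (not significant)"
reovirus,not_graded,,0,,"Table 3, platinum-resistant: oncolytic reovirus plus paclitaxel (not significant)"
pazopanib,not_graded,,0,,"Table 3, platinum-resistant: pazopanib plus paclitaxel (not significant)"
cabozantinib,not_graded,,0,,"Table 3, platinum-resistant: cabozantinib plus paclitaxel (control arm significantly better OS)"
olaratumab,not_graded,,0,,"Table 3, platinum-resistant: olaratumab plus PLD (not significant)"
linsitinib,not_graded,,0,,"Table 3, platinum-resistant: linsitinib plus paclitaxel (not significant)"
alisertib,not_graded,,0,,"Table 3, platinum-resistant: alisertib plus paclitaxel (did not meet criteria for significance)"
guadecitabine,not_graded,,0,,"Table 3, platinum-resistant: carboplatin plus guadecitabine (not significant)"
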