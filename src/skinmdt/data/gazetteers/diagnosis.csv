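term,rule_id,attribute,value
basal cell carcinoma,dx_bcc,diagnosis,bcc
bcc,dx_bcc_abbrev,diagnosis,bcc
rodent ulcer,dx_bcc_rodent,diagnosis,bcc
basalioma,dx_bcc_basalioma,diagnosis,bcc
nodular basal cell carcinoma,dx_bcc_nodular,diagnosis,bcc:nodular
superficial basal cell carcinoma,dx_bcc_superficial,diagnosis,bcc:superficial
infiltrative basal cell carcinoma,dx_bcc_infiltrative,diagnosis,bcc:infiltrative
micronodular basal cell carcinoma,dx_bcc_micronodular,diagnosis,bcc:micronodular
morphoeic basal cell carcinoma,dx_bcc_morphoeic,diagnosis,bcc:morphoeic
nodular bcc,dx_bcc_nodular_abbrev,diagnosis,bcc:nodular
superficial bcc,dx_bcc_superficial_abbrev,diagnosis,bcc:superficial
infiltrative bcc,dx_bcc_infiltrative_abbrev,diagnosis,bcc:infiltrative
micronodular bcc,dx_bcc_micronodular_abbrev,diagnosis,bcc:micronodular
morphoeic bcc,dx_bcc_morphoeic_abbrev,diagnosis,bcc:morphoeic
squamous cell carcinoma,dx_scc,diagnosis,other_cancer
invasive squamous cell carcinoma,dx_scc_invasive,diagnosis,other_cancer
malignant melanoma,dx_melanoma,diagnosis,other_cancer
melanoma,dx_melanoma_short,diagnosis,other_cancer
merkel cell carcinoma,dx_merkel,diagnosis,other_cancer
squamous cell carcinoma in situ,dx_scc_in_situ,diagnosis,other_in_situ
melanoma in situ,dx_melanoma_in_situ,diagnosis,other_in_situ
bowen's disease,dx_bowens,diagnosis,other_in_situ
bowens disease,dx_bowens_plain,diagnosis,other_in_situ
carcinoma in situ,dx_cis,diagnosis,other_in_situ
lentigo maligna,dx_lentigo_maligna,diagnosis,other_in_situ
keratoacanthoma,dx_keratoacanthoma,diagnosis,other_intermediate
atypical fibroxanthoma,dx_afx,diagnosis,other_intermediate
seborrhoeic keratosis,dx_seb_k,diagnosis,benign
seborrheic keratosis,dx_seb_k_us,diagnosis,benign
intradermal naevus,dx_id_naevus,diagnosis,benign
intradermal nevus,dx_id_naevus_us,diagnosis,benign
compound naevus,dx_compound_naevus,diagnosis,benign
compound nevus,dx_compound_naevus_us,diagnosis,benign
dermatofibroma,dx_dermatofibroma,diagnosis,benign
benign lichenoid keratosis,dx_blk,diagnosis,benign
actinic keratosis,dx_actinic_keratosis,diagnosis,benign
fibroepithelial polyp,dx_fep,diagnosis,benign
epidermal cyst,dx_epidermal_cyst,diagnosis,benign
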