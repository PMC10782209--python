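term,rule_id,attribute,value
punch biopsy,ex_punch,excision_type,punch_biopsy
skin punch biopsy,ex_punch_skin,excision_type,punch_biopsy
incision biopsy,ex_incision,excision_type,incision_biopsy
incisional biopsy,ex_incisional,excision_type,incision_biopsy
shave biopsy,ex_shave,excision_type,shave_biopsy
superficial shave biopsy,ex_shave_superficial,excision_type,shave_biopsy
curettage,ex_curettage,excision_type,curettage
curettings,ex_curettings,excision_type,curettage
excision,ex_excision,excision_type,excision
wide local excision,ex_wle,excision_type,excision
re-excision,ex_re_excision,excision_type,excision
ellipse,ex_ellipse,excision_type,excision
ellipse of skin,ex_ellipse_skin,excision_type,excision
excision biopsy,ex_excision_biopsy,excision_type,excision
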