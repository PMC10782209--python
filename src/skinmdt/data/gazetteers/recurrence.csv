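term,rule_id,attribute,value
recurrent,rc_recurrent,recurrence,true
recurrence,rc_recurrence,recurrence,true
previously excised,rc_previously_excised,recurrence,true
re-presentation,rc_re_presentation,recurrence,true
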