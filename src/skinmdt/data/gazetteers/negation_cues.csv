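term,rule_id,attribute,value
no evidence of,neg_no_evidence,negation,cue
no residual,neg_no_residual,negation,cue
negative for,neg_negative_for,negation,cue
not seen,neg_not_seen,negation,cue
free of,neg_free_of,negation,cue
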