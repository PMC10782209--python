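term,rule_id,attribute,value
completely excised,mg_complete,margin,both:clear
excision is complete,mg_complete_alt,margin,both:clear
excision appears complete,mg_complete_appears,margin,both:clear
clear of all margins,mg_clear_all,margin,both:clear
incompletely excised,mg_incomplete,margin,both:involved
excision is incomplete,mg_incomplete_alt,margin,both:involved
extends to the peripheral margin,mg_periph_extends,margin,peripheral:involved
reaches the peripheral margin,mg_periph_reaches,margin,peripheral:involved
involves the peripheral margin,mg_periph_involves,margin,peripheral:involved
peripheral margin involved,mg_periph_involved,margin,peripheral:involved
peripheral margin is involved,mg_periph_is_involved,margin,peripheral:involved
extends to the deep margin,mg_deep_extends,margin,deep:involved
reaches the deep margin,mg_deep_reaches,margin,deep:involved
involves the deep margin,mg_deep_involves,margin,deep:involved
deep margin involved,mg_deep_involved,margin,deep:involved
deep margin is involved,mg_deep_is_involved,margin,deep:involved
peripheral margin is clear,mg_periph_clear,margin,peripheral:clear
peripheral margin clear,mg_periph_clear_short,margin,peripheral:clear
deep margin is clear,mg_deep_clear,margin,deep:clear
deep margin clear,mg_deep_clear_short,margin,deep:clear
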