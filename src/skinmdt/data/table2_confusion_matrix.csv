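prediction\reference,Follow-up 6-monthly for 5 years,"Further excisional surgery, destructive surgical or non-surgical technique recommended to obtain oncological clearance",No follow-up,Offer re-excision. If declined follow-up 6-monthly for 2 years,"Other cancerous, in situ or intermediate lesion. Review of histopathology free text required to guide management"
Follow-up 6-monthly for 5 years,138,7,12,11,3
"Further excisional surgery, destructive surgical or non-surgical technique recommended to obtain oncological clearance",0,17,1,1,0
No follow-up,8,7,745,20,4
Offer re-excision. If declined follow-up 6-monthly for 2 years,0,0,5,12,0
"Other cancerous, in situ or intermediate lesion. Review of histopathology free text required to guide management",0,0,7,1,46
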