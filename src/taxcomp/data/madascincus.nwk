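(((((polleni-N_1,polleni-N_2),polleni-N_3),(polleni-S_1,polleni-S_2)),(((stumpffi_1,stumpffi_2),((stumpffi_3,stumpffi_4),stumpffi_5)),(arenicola_1,arenicola_2))),(((mouroundavae_1,mouroundavae_2),(((igneocaudatus-S_1,igneocaudatus-S_2),(igneocaudatus-S_3,igneocaudatus-S_4)),(igneocaudatus-C_1,igneocaudatus-C_2))),((((melanopleura-N_1,melanopleura-N_2),((melanopleura-N_3,melanopleura-N_4),melanopleura-N_5)),(((melanopleura-C_1,melanopleura-C_2),(melanopleura-C_3,melanopleura-C_4)),((melanopleura-S_1,melanopleura-S_2),(melanopleura-S_3,melanopleura-S_4)))),nanus_1)));
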