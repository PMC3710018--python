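specimen	MTMC	ITAX	WP	BAT	HW	BSD	GMYC
polleni-N_1	polleni-N	polleni-N	polleni-N-1	polleni-N	polleni-group	polleni-N-1	polleni-N_1
polleni-N_2	polleni-N	polleni-N	polleni-N-1	polleni-N	polleni-group	polleni-N-1	polleni-N_2
polleni-N_3	polleni-N	polleni-N	polleni-N-2	polleni-N	polleni-group	polleni-N-2	polleni-N_3
polleni-S_1	polleni-S	polleni-S	polleni-S-1	polleni-S	polleni-group	polleni-S-1	polleni-S_1
polleni-S_2	polleni-S	polleni-S	polleni-S-2	polleni-S	polleni-group	polleni-S-2	polleni-S_2
stumpffi_1	stumpffi	stumpffi	stumpffi-1	stumpffi	polleni-group	stumpffi-1	stumpffi_1
stumpffi_2	stumpffi	stumpffi	stumpffi-1	stumpffi	polleni-group	stumpffi-1	stumpffi_2
stumpffi_3	stumpffi	stumpffi	stumpffi-2	stumpffi	polleni-group	stumpffi-2	stumpffi_3
stumpffi_4	stumpffi	stumpffi	stumpffi-2	stumpffi	polleni-group	stumpffi-2	stumpffi_4
stumpffi_5	stumpffi	stumpffi	stumpffi-3	stumpffi	polleni-group	stumpffi-3	stumpffi_5
arenicola_1	arenicola	arenicola	arenicola	arenicola	polleni-group	arenicola	arenicola_1
arenicola_2	arenicola	arenicola	arenicola	arenicola	polleni-group	arenicola	arenicola_2
mouroundavae_1	mouroundavae	mouroundavae	mouroundavae	mouroundavae	mouroundavae-1	mouroundavae	mouroundavae_1
mouroundavae_2	mouroundavae	mouroundavae	mouroundavae	mouroundavae	mouroundavae-2	mouroundavae	mouroundavae_2
igneocaudatus-S_1	igneocaudatus-S	igneocaudatus-S	igneocaudatus-S	igneocaudatus-S	igneocaudatus-S-1	igneocaudatus-S-1	igneocaudatus-S_1
igneocaudatus-S_2	igneocaudatus-S	igneocaudatus-S	igneocaudatus-S	igneocaudatus-S	igneocaudatus-S-1	igneocaudatus-S-1	igneocaudatus-S_2
igneocaudatus-S_3	igneocaudatus-S	igneocaudatus-S	igneocaudatus-S	igneocaudatus-S	igneocaudatus-S-2	igneocaudatus-S-2	igneocaudatus-S_3
igneocaudatus-S_4	igneocaudatus-S	igneocaudatus-S	igneocaudatus-S	igneocaudatus-S	igneocaudatus-S-2	igneocaudatus-S-2	igneocaudatus-S_4
igneocaudatus-C_1	igneocaudatus-C	igneocaudatus-C	igneocaudatus-C	igneocaudatus-C	igneocaudatus-C	igneocaudatus-C	igneocaudatus-C_1
igneocaudatus-C_2	igneocaudatus-C	igneocaudatus-C	igneocaudatus-C	igneocaudatus-C	igneocaudatus-C	igneocaudatus-C	igneocaudatus-C_2
melanopleura-N_1	melanopleura	melanopleura-N-1	melanopleura	melanopleura-N	melanopleura-N-1	melanopleura-N-1	melanopleura-N_1
melanopleura-N_2	melanopleura	melanopleura-N-1	melanopleura	melanopleura-N	melanopleura-N-1	melanopleura-N-1	melanopleura-N_2
melanopleura-N_3	melanopleura	melanopleura-N-2	melanopleura	melanopleura-N	melanopleura-N-2	melanopleura-N-2	melanopleura-N_3
melanopleura-N_4	melanopleura	melanopleura-N-2	melanopleura	melanopleura-N	melanopleura-N-2	melanopleura-N-2	melanopleura-N_4
melanopleura-N_5	melanopleura	melanopleura-N-2	melanopleura	melanopleura-N	melanopleura-N-2	melanopleura-N-3	melanopleura-N_5
melanopleura-C_1	melanopleura	melanopleura-C	melanopleura	melanopleura-C	melanopleura-C-1	melanopleura-C-1	melanopleura-C_1
melanopleura-C_2	melanopleura	melanopleura-C	melanopleura	melanopleura-C	melanopleura-C-1	melanopleura-C-1	melanopleura-C_2
melanopleura-C_3	melanopleura	melanopleura-C	melanopleura	melanopleura-C	melanopleura-C-2	melanopleura-C-2	melanopleura-C_3
melanopleura-C_4	melanopleura	melanopleura-C	melanopleura	melanopleura-C	melanopleura-C-2	melanopleura-C-2	melanopleura-C_4
melanopleura-S_1	melanopleura	melanopleura-S	melanopleura	melanopleura-S	melanopleura-S-1	melanopleura-S-1	melanopleura-S_1
melanopleura-S_2	melanopleura	melanopleura-S	melanopleura	melanopleura-S	melanopleura-S-1	melanopleura-S-1	melanopleura-S_2
melanopleura-S_3	melanopleura	melanopleura-S	melanopleura	melanopleura-S	melanopleura-S-2	melanopleura-S-2	melanopleura-S_3
melanopleura-S_4	melanopleura	melanopleura-S	melanopleura	melanopleura-S	melanopleura-S-2	melanopleura-S-2	melanopleura-S_4
nanus_1	nanus	nanus	nanus	nanus	nanus	nanus	nanus_1
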