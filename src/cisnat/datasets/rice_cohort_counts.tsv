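key	value
candidate_pairs	5813
total_pairs	3819
total_transcripts	76013
one_to_one_pairs	3358
network_pairs	461
network_transcripts	685
network_groups	223
one_to_two_groups	209
one_to_three_groups	9
two_to_two_groups	4
one_to_four_groups	1
expressed_pairs	2292
expressed_control	1789
expressed_salt	1572
expressed_cold	1668
expressed_drought	1668
coexpressed_pairs	1072
stress_preferential_pairs	503
epidermal_pairs	1238
epidermal_coexpressed	725
exclusive_pairs	166
enriched_pairs	13
deg_pairs	112
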