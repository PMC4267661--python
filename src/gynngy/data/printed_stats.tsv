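stat	species	value	note
as_region_chisq_p_printed_table	human	2.2e-16	reporting floor; contrast [[621,106600],[175,14802]]
as_region_chisq_p_printed_table	mouse	3.861e-14	table value; the text of the same source prints 8.36e-11 for this contrast
as_region_chisq_p_printed_text	mouse	8.36e-11	text value; disagrees with the table value, both recorded without adjudication
strong_vs_others_conservation_fisher_p	human	1.311e-4	strong class against pooled other classes
strong_vs_others_conservation_fisher_p	mouse	1.262e-2	strong class against pooled other classes
strong_by_region_p	human	1.094e-8	chi-squared, UTR vs CDS strong proportions
strong_by_region_p	mouse	2.689e-2	Fisher's exact, UTR vs CDS strong proportions
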