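# SYNTHETIC illustrative structure-function catalog.
# These entries were generated from a log-linear model (slope -0.4 per
# hydrogen-bonding residue, lognormal scatter) purely to demonstrate the
# catalog-fit tooling. They are NOT experimental measurements and must
# not be cited as such.
name	N	N_H	pf_cm3_s	dG_kcal_mol	quality
nanotube_like	3	0	3.2e-12		direct_count
short_file_A	4	4	6.1e-13		direct_count
mid_file_B	6	8	1.4e-13		direct_count
long_file_C	8	10	5.5e-14		direct_count
long_file_D	8	12	1.9e-14		direct_count
biochem_E	7	14	1.1e-14		estimated
gated_F	8	16	9.0e-17		direct_count
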