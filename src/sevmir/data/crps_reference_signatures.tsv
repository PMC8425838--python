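study_id	sample_type	comparison	treatment	mirnas
mcdonald2014_exosome	exosome	CRPS_vs_control	untreated	miR-15a-5p,miR-22-3p,miR-26b-5p,miR-31-5p,miR-93-5p,miR-130b-3p,miR-339-5p,miR-744-5p
douglas2015_orlova2011_wholeblood	whole_blood	CRPS_vs_control	untreated	let-7a-5p,let-7c-5p,let-7d-5p,let-7g-5p,miR-16-5p,miR-18a-5p,miR-25-3p,miR-26b-5p,miR-29b-3p,miR-93-5p,miR-106b-5p,miR-107,miR-130b-3p,miR-142-5p,miR-148b-3p,miR-185-5p,miR-191-5p,miR-221-3p,miR-320a,miR-340-5p,miR-484,miR-652-3p
douglas2015_ketamine_wholeblood	whole_blood	pre_post_treatment	ketamine	let-7a-5p,let-7c-5p,let-7d-5p,let-7e-5p,let-7f-5p,let-7g-5p,miR-15a-5p,miR-15b-5p,miR-16-5p,miR-18a-5p,miR-19b-3p,miR-25-3p,miR-26a-5p,miR-26b-5p,miR-27a-3p,miR-29b-3p,miR-92a-3p,miR-106a-5p,miR-107,miR-148b-3p,miR-191-5p,miR-222-3p,miR-320a,miR-339-5p,miR-340-5p,miR-484,miR-486-5p
ramanathan2019_plasma_exchange_exosome	exosome	pre_post_treatment	plasma_exchange	miR-16-5p,miR-26b-5p,miR-148b-3p
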