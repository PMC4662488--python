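subject_id	group	age	tnm	localization
T1	case	57	T4N2M0	Oropharynx
T2	case	46	T3N1M0	Oropharynx
T3	case	61	T3N2M0	Oropharynx
T4	case	63	T3N1M0	Oropharynx
T5	case	58	T2N1M0	Oral
T6	case	63	T4N1M0	Oropharynx and Larynx
T7	case	46	T4N0M0	Oral and Oropharynx
N1	control	64	N/A	N/A
N2	control	64	N/A	N/A
N3	control	66	N/A	N/A
N4	control	68	N/A	N/A
N5	control	69	N/A	N/A
N6	control	61	N/A	N/A
N7	control	66	N/A	N/A
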