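virus_name	abbreviation	genome_type	family	segment_label	genome_length	accession
Ceratitis capitata iflavirus 1	CcaIV1	positive_ssRNA	Iflaviridae		10502	GAMC01001920.1
Ceratitis capitata iflavirus 2	CcaIV2	positive_ssRNA	Iflaviridae		10332	OL957305
Ceratitis capitata iflavirus 3	CcaIV3	positive_ssRNA	Iflaviridae		7370	HG994137
Ceratitis capitata iflavirus 4	CcaIV4	positive_ssRNA	Iflaviridae		9023	HG994138
Ceratitis capitata narnavirus 1	CcaNaV1	positive_ssRNA	Narnaviridae		2896	OL957306
Ceratitis capitata nodavirus 1	CcaNdV1	positive_ssRNA	Nodaviridae	segment 1	3092	OL957308
Ceratitis capitata nodavirus 1	CcaNdV1	positive_ssRNA	Nodaviridae	segment 2	1798	OL957309
Ceratitis capitata negev-like virus 1	CcaNeLV1	positive_ssRNA	Negeviridae		10258	HG994139
Ceratitis capitata negev-like virus 2	CcaNeLV2	positive_ssRNA	Negeviridae		10506	OL957307
Ceratitis capitata nora virus	CcaNV	positive_ssRNA	Unclassified Riboviria		12014	GAMC01015827.1
Ceratitis capitata virga-like virus 1	CcaViLV1	positive_ssRNA	Virgaviridae		9925	GAMC01017950.1
Ceratitis capitata sigmavirus	CcaSV	negative_ssRNA	Rhabdoviridae		12583	KR822825.1
Ceratitis capitata reo-like virus 1	CcaRLV1	dsRNA	Reoviridae	segment 1	4177	OL957310
Ceratitis capitata reo-like virus 1	CcaRLV1	dsRNA	Reoviridae	segment 2	3857	OL957311
Ceratitis capitata reo-like virus 1	CcaRLV1	dsRNA	Reoviridae	segment 3	3141	OL957312
Ceratitis capitata totivirus 1	CcaTV1	dsRNA	Totiviridae		6132	OL957313
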