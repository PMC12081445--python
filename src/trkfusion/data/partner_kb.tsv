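#version	kb-2024.1
#tkd_region	NTRK1	12	17
#tkd_region	NTRK2	16	20
#tkd_region	NTRK3	15	19
partner_gene	ntrk_gene	evidence_class	source_tags
LMNA	NTRK1	canonical	COSMIC,GENIE
PEAR1	NTRK1	canonical	COSMIC
RABGAP1L	NTRK1	canonical	GENIE
TP53	NTRK1	canonical	COSMIC
EML4	NTRK1	canonical	COSMIC,GENIE
TPM3	NTRK1	canonical	COSMIC,GENIE
LGR6	NTRK1	clinical_validity	larotrectinib-trials
TPR	NTRK1	canonical	COSMIC
IRF2BP2	NTRK1	canonical	GENIE
GKAP1	NTRK2	canonical	COSMIC
SQSTM1	NTRK2	canonical	COSMIC,GENIE
GNAQ	NTRK2	canonical	COSMIC
SASH1	NTRK3	canonical	GENIE
ETV6	NTRK3	canonical	COSMIC,GENIE
EML4	NTRK3	canonical	COSMIC
ARNT2	NTRK3	canonical	GENIE
SQSTM1	NTRK3	canonical	COSMIC
TARSL2	NTRK3	clinical_validity	entrectinib-trials
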