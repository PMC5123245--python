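gene	members
MT-TA	8-14
MT-TA	9-12-23
MT-TA	10-25-45
MT-TA	13-22-46
MT-TA	15-48
MT-TA	26-44
MT-TA	54-58
MT-TC	8-14
MT-TC	9-12-23
MT-TC	10-25-45
MT-TC	15-48
MT-TC	26-44
MT-TC	54-58
MT-TD	8-14
MT-TD	9-12-23
MT-TD	10-25-45
MT-TD	13-22-46
MT-TD	15-48
MT-TD	18-55
MT-TD	19-56
MT-TD	26-44
MT-TD	54-58
MT-TE	8-14
MT-TE	9-12-23
MT-TE	10-25-45
MT-TE	13-22-46
MT-TE	15-48
MT-TE	18-55
MT-TE	19-56
MT-TE	26-44
MT-TE	54-58
MT-TF	8-14
MT-TF	9-12-23
MT-TF	10-25-45
MT-TF	13-22-46
MT-TF	15-48
MT-TF	26-44
MT-TF	54-58
MT-TG	8-14
MT-TG	9-12-23
MT-TG	10-25-45
MT-TG	13-22-46
MT-TG	15-48
MT-TG	26-44
MT-TG	54-58
MT-TH	8-14
MT-TH	9-12-23
MT-TH	10-25-45
MT-TH	13-22-46
MT-TH	15-48
MT-TH	26-44
MT-TH	54-58
MT-TI	8-14
MT-TI	9-12-23
MT-TI	10-25-45
MT-TI	13-22-46
MT-TI	15-48
MT-TI	26-44
MT-TI	54-58
MT-TK	8-14
MT-TK	9-12-23
MT-TK	10-25-45
MT-TK	13-22-46
MT-TK	15-48
MT-TK	26-44
MT-TK	54-58
MT-TL1	8-14
MT-TL1	9-12-23
MT-TL1	10-25-45
MT-TL1	13-22-46
MT-TL1	15-48
MT-TL1	18-55
MT-TL1	19-56
MT-TL1	26-44
MT-TL1	54-58
MT-TL2	8-14
MT-TL2	9-12-23
MT-TL2	10-25-45
MT-TL2	13-22-46
MT-TL2	15-48
MT-TL2	18-55
MT-TL2	19-56
MT-TL2	26-44
MT-TL2	54-58
MT-TM	8-14
MT-TM	9-12-23
MT-TM	10-25-45
MT-TM	13-22-46
MT-TM	15-48
MT-TM	26-44
MT-TM	54-58
MT-TN	8-14
MT-TN	9-12-23
MT-TN	10-25-45
MT-TN	13-22-46
MT-TN	15-48
MT-TN	26-44
MT-TN	54-58
MT-TP	8-14
MT-TP	9-12-23
MT-TP	10-25-45
MT-TP	13-22-46
MT-TP	15-48
MT-TP	26-44
MT-TP	54-58
MT-TQ	8-14
MT-TQ	9-12-23
MT-TQ	10-25-45
MT-TQ	13-22-46
MT-TQ	15-48
MT-TQ	18-55
MT-TQ	19-56
MT-TQ	26-44
MT-TQ	54-58
MT-TR	8-14
MT-TR	9-12-23
MT-TR	10-25-45
MT-TR	15-48
MT-TR	26-44
MT-TR	54-58
MT-TS1	8-14
MT-TS1	9-12-23
MT-TS1	10-25-45
MT-TS1	13-22-46
MT-TS1	15-48
MT-TS1	26-44
MT-TS1	54-58
MT-TS2	8-14
MT-TS2	15-48
MT-TS2	26-44
MT-TS2	54-58
MT-TT	8-14
MT-TT	9-12-23
MT-TT	10-25-45
MT-TT	15-48
MT-TT	26-44
MT-TT	54-58
MT-TV	8-14
MT-TV	9-12-23
MT-TV	10-25-45
MT-TV	13-22-46
MT-TV	15-48
MT-TV	18-55
MT-TV	19-56
MT-TV	26-44
MT-TV	54-58
MT-TW	8-14
MT-TW	9-12-23
MT-TW	10-25-45
MT-TW	13-22-46
MT-TW	15-48
MT-TW	26-44
MT-TW	54-58
MT-TY	8-14
MT-TY	9-12-23
MT-TY	10-25-45
MT-TY	15-48
MT-TY	26-44
MT-TY	54-58
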