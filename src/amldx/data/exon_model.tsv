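# gene	exon_index	coding_length
CBFA2T2	1	288
CBFA2T2	2	318
CBFA2T2	3	117
CBFA2T2	4	132
CBFA2T2	5	213
CBFA2T2	6	240
CBFA2T2	7	294
CBFA2T2	8	189
CBFA2T2	9	99
CBFA2T2	10	147
CBFA2T2	11	213
CBFA2T2	12	192
CBFA2T3	1	336
CBFA2T3	2	204
CBFA2T3	3	261
CBFA2T3	4	255
CBFA2T3	5	114
CBFA2T3	6	288
CBFA2T3	7	102
CBFA2T3	8	93
CBFA2T3	9	246
CBFA2T3	10	156
CBFA2T3	11	186
CBFA2T3	12	252
CBFB	1	132
CBFB	2	111
CBFB	3	279
CBFB	4	357
CBFB	5	273
CBFB	6	312
CBL	1	201
CBL	2	99
CBL	3	264
CBL	4	243
CBL	5	291
CBL	6	252
CBL	7	219
CBL	8	90
CBL	9	276
CBL	10	138
CBL	11	219
CBL	12	132
CBL	13	243
CBL	14	213
CBL	15	198
CBL	16	243
CNTRL	1	126
CNTRL	2	210
CNTRL	3	282
CNTRL	4	336
CNTRL	5	147
CNTRL	6	309
CNTRL	7	180
CNTRL	8	198
CNTRL	9	306
CNTRL	10	144
CNTRL	11	156
CNTRL	12	186
CNTRL	13	264
CNTRL	14	321
CNTRL	15	162
CNTRL	16	183
CNTRL	17	321
CNTRL	18	357
CNTRL	19	300
CNTRL	20	240
DEK	1	306
DEK	2	153
DEK	3	132
DEK	4	267
DEK	5	156
DEK	6	267
DEK	7	150
DEK	8	228
DEK	9	309
DEK	10	165
ELL	1	240
ELL	2	258
ELL	3	147
ELL	4	219
ELL	5	288
ELL	6	264
ELL	7	270
ELL	8	234
ELL	9	339
ELL	10	120
ELL	11	225
ELL	12	333
EVX1	1	201
EVX1	2	93
EVX1	3	354
EVX1	4	171
GLIS2	1	102
GLIS2	2	135
GLIS2	3	348
GLIS2	4	180
GLIS2	5	93
GLIS2	6	255
HOXA10	1	102
HOXA10	2	237
HOXA13	1	258
HOXA13	2	282
HSPA8	1	117
HSPA8	2	222
HSPA8	3	231
HSPA8	4	315
HSPA8	5	90
HSPA8	6	183
HSPA8	7	198
HSPA8	8	237
KDM5A	1	300
KDM5A	2	225
KDM5A	3	294
KDM5A	4	93
KDM5A	5	168
KDM5A	6	150
KDM5A	7	249
KDM5A	8	111
KDM5A	9	183
KDM5A	10	156
KDM5A	11	342
KDM5A	12	90
KDM5A	13	267
KDM5A	14	168
KIT	1	321
KIT	2	189
KIT	3	90
KIT	4	264
KIT	5	135
KIT	6	315
KIT	7	318
KIT	8	201
KIT	9	210
KIT	10	258
KIT	11	156
KIT	12	228
KIT	13	357
KIT	14	150
KIT	15	240
KIT	16	141
KIT	17	303
KIT	18	210
KIT	19	297
KIT	20	303
KIT	21	333
KMT2A	1	249
KMT2A	2	228
KMT2A	3	276
KMT2A	4	141
KMT2A	5	285
KMT2A	6	144
KMT2A	7	255
KMT2A	8	285
KMT2A	9	153
KMT2A	10	162
KMT2A	11	207
KMT2A	12	117
KMT2A	13	228
KMT2A	14	144
KMT2A	15	93
KMT2A	16	114
MECOM	1	168
MECOM	2	240
MECOM	3	186
MECOM	4	147
MECOM	5	90
MECOM	6	204
MECOM	7	240
MECOM	8	267
MECOM	9	237
MECOM	10	168
MECOM	11	114
MECOM	12	246
MECOM	13	156
MECOM	14	102
MECOM	15	333
MECOM	16	228
MLLT10	1	207
MLLT10	2	141
MLLT10	3	159
MLLT10	4	231
MLLT10	5	321
MLLT10	6	99
MLLT10	7	213
MLLT10	8	96
MLLT10	9	258
MLLT10	10	336
MLLT10	11	333
MLLT10	12	234
MLLT10	13	237
MLLT10	14	213
MLLT10	15	132
MLLT10	16	96
MLLT10	17	282
MLLT10	18	102
MLLT3	1	342
MLLT3	2	297
MLLT3	3	201
MLLT3	4	333
MLLT3	5	267
MLLT3	6	228
MLLT3	7	324
MLLT3	8	177
MLLT3	9	132
MLLT3	10	195
MRTFA	1	300
MRTFA	2	252
MRTFA	3	216
MRTFA	4	192
MRTFA	5	237
MRTFA	6	330
MRTFA	7	339
MRTFA	8	177
MRTFA	9	309
MRTFA	10	354
MRTFA	11	126
MRTFA	12	174
MRTFA	13	201
MRTFA	14	207
MYH11	1	270
MYH11	2	120
MYH11	3	309
MYH11	4	201
MYH11	5	132
MYH11	6	138
MYH11	7	279
MYH11	8	306
MYH11	9	228
MYH11	10	192
MYH11	11	108
MYH11	12	258
MYH11	13	228
MYH11	14	96
MYH11	15	210
MYH11	16	156
MYH11	17	207
MYH11	18	210
MYH11	19	162
MYH11	20	219
NSD1	1	186
NSD1	2	288
NSD1	3	294
NSD1	4	204
NSD1	5	180
NSD1	6	96
NSD1	7	321
NSD1	8	192
NSD1	9	279
NSD1	10	159
NSD1	11	291
NSD1	12	222
NUP214	1	198
NUP214	2	270
NUP214	3	135
NUP214	4	270
NUP214	5	90
NUP214	6	351
NUP214	7	198
NUP214	8	342
NUP214	9	213
NUP214	10	198
NUP214	11	192
NUP214	12	156
NUP214	13	117
NUP214	14	117
NUP214	15	99
NUP214	16	267
NUP214	17	324
NUP214	18	96
NUP214	19	195
NUP214	20	309
NUP98	1	324
NUP98	2	201
NUP98	3	312
NUP98	4	252
NUP98	5	243
NUP98	6	180
NUP98	7	321
NUP98	8	150
NUP98	9	345
NUP98	10	93
NUP98	11	261
NUP98	12	315
NUP98	13	90
NUP98	14	309
NUP98	15	261
NUP98	16	132
NUP98	17	222
NUP98	18	144
NUP98	19	303
NUP98	20	258
PLEK	1	186
PLEK	2	252
PLEK	3	276
PLEK	4	270
PLEK	5	186
PLEK	6	306
PLEK	7	246
PLEK	8	93
PLEK	9	210
PLEK	10	195
PML	1	144
PML	2	318
PML	3	174
PML	4	99
PML	5	105
PML	6	147
PML	7	258
PML	8	150
PML	9	330
POU2F2	1	114
POU2F2	2	249
POU2F2	3	348
POU2F2	4	135
POU2F2	5	354
POU2F2	6	234
POU2F2	7	255
POU2F2	8	159
POU2F2	9	255
POU2F2	10	192
PRDM16	1	174
PRDM16	2	90
PRDM16	3	189
PRDM16	4	348
PRDM16	5	252
PRDM16	6	231
PRDM16	7	258
PRDM16	8	243
PRDM16	9	132
PRDM16	10	114
PRDM16	11	342
PRDM16	12	123
PRDM16	13	276
PRDM16	14	327
PRDM16	15	192
PRDM16	16	318
PRDM16	17	312
RARA	1	270
RARA	2	261
RARA	3	276
RARA	4	255
RARA	5	339
RARA	6	279
RARA	7	270
RARA	8	264
RARA	9	252
RBM15	1	195
RBM15	2	129
RBM15	3	258
RBM15	4	150
RUNX1	1	249
RUNX1	2	147
RUNX1	3	222
RUNX1	4	99
RUNX1	5	234
RUNX1	6	201
RUNX1	7	120
RUNX1	8	102
RUNX1T1	1	324
RUNX1T1	2	333
RUNX1T1	3	111
RUNX1T1	4	258
RUNX1T1	5	267
RUNX1T1	6	180
RUNX1T1	7	201
RUNX1T1	8	159
RUNX1T1	9	240
RUNX1T1	10	288
RUNX1T1	11	354
RUNX1T1	12	330
TEC	1	279
TEC	2	357
TEC	3	105
TEC	4	111
TEC	5	132
TEC	6	210
TEC	7	219
TEC	8	351
TEC	9	117
TEC	10	246
TEC	11	216
TEC	12	306
TEC	13	246
TEC	14	192
UBTF	1	279
UBTF	2	324
UBTF	3	261
UBTF	4	348
UBTF	5	165
UBTF	6	162
UBTF	7	354
UBTF	8	180
UBTF	9	270
UBTF	10	201
UBTF	11	324
UBTF	12	348
UBTF	13	336
UBTF	14	108
UBTF	15	192
UBTF	16	252
UBTF	17	198
UBTF	18	243
UBTF	19	330
UBTF	20	297
UBTF	21	162
USP42	1	111
USP42	2	183
USP42	3	132
USP42	4	225
USP42	5	303
USP42	6	105
USP42	7	345
USP42	8	333
USP42	9	234
USP42	10	303
USP42	11	228
USP42	12	309
ZEB2	1	279
ZEB2	2	156
ZEB2	3	141
ZEB2	4	177
ZEB2	5	312
ZEB2	6	105
ZEB2	7	96
ZEB2	8	339
ZEB2	9	258
ZEB2	10	144
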