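ʃupɔ	ʃ u p ɔ	120000
kegona	k e g o n a	57956
neno	n e n o	37862
vapida	v a p i d a	27991
bɔko	b ɔ k o	22144
pesela	p e s e l a	18286
fopu	f o p u	15554
t͡ʃe	t͡ʃ e	13519
teʎe	t e ʎ e	11946
bodapo	b o d a p o	10695
noɾu	n o ɾ u	9677
mode	m o d e	8832
ʒini	ʒ i n i	8120
ɾa	ɾ a	7512
kudɔ	k u d ɔ	6987
ma	m a	6529
to	t o	6126
kame	k a m e	5770
ɲide	ɲ i d e	5451
ɾɔkumi	ɾ ɔ k u m i	5165
fapo	f a p o	4907
mema	m e m a	4673
tona	t o n a	4460
vopu	v o p u	4265
di	d i	4086
d͡ʒabo	d͡ʒ a b o	3922
nad͡ʒo	n a d͡ʒ o	3769
kuɲa	k u ɲ a	3628
zuʎaʃa	z u ʎ a ʃ a	3497
nuɲo	n u ɲ o	3374
ti	t i	3260
suloma	s u l o m a	3153
nuti	n u t i	3053
tibi	t i b i	2959
kitame	k i t a m e	2870
nasokɔ	n a s o k ɔ	2787
ɾape	ɾ a p e	2708
d͡ʒovu	d͡ʒ o v u	2633
ʒoʃe	ʒ o ʃ e	2562
si	s i	2495
duno	d u n o	2431
vo	v o	2370
budo	b u d o	2312
diki	d i k i	2257
ʒimat͡ʃo	ʒ i m a t͡ʃ o	2204
seme	s e m e	2154
la	l a	2106
na	n a	2060
mɛ	m ɛ	2016
ɾekɔ	ɾ e k ɔ	1974
zoɾu	z o ɾ u	1933
ʃuʎobɛ	ʃ u ʎ o b ɛ	1894
ɾime	ɾ i m e	1856
d͡ʒuɲu	d͡ʒ u ɲ u	1820
kɛki	k ɛ k i	1786
sipini	s i p i n i	1752
ɾese	ɾ e s e	1720
nusi	n u s i	1689
ɾaʎiʁa	ɾ a ʎ i ʁ a	1659
movi	m o v i	1630
ɾemu	ɾ e m u	1602
neke	n e k e	1575
bu	b u	1548
nuɾu	n u ɾ u	1523
va	v a	1498
ɾaba	ɾ a b a	1475
fude	f u d e	1451
kosi	k o s i	1429
nuɾike	n u ɾ i k e	1407
sopɔ	s o p ɔ	1386
voʒo	v o ʒ o	1366
ɲɛkɔ	ɲ ɛ k ɔ	1346
dɔni	d ɔ n i	1326
ʒa	ʒ a	1308
dema	d e m a	1289
tikɛtu	t i k ɛ t u	1272
kuta	k u t a	1254
situt͡ʃi	s i t u t͡ʃ i	1237
kiɲe	k i ɲ e	1221
sasi	s a s i	1205
tɔte	t ɔ t e	1189
nudɔ	n u d ɔ	1174
natɔ	n a t ɔ	1159
keviku	k e v i k u	1145
ke	k e	1131
ɾevi	ɾ e v i	1117
gume	g u m e	1103
ʎopovo	ʎ o p o v o	1090
t͡ʃoga	t͡ʃ o g a	1077
keno	k e n o	1065
t͡ʃukose	t͡ʃ u k o s e	1052
ʎado	ʎ a d o	1040
teni	t e n i	1029
da	d a	1017
miɾa	m i ɾ a	1006
nupu	n u p u	995
tuɾa	t u ɾ a	984
ɾuʎi	ɾ u ʎ i	974
mitu	m i t u	963
ʃɔdi	ʃ ɔ d i	953
dutuʒo	d u t u ʒ o	943
kebi	k e b i	934
nɔtɛ	n ɔ t ɛ	924
ʁobɔma	ʁ o b ɔ m a	915
samo	s a m o	906
tazu	t a z u	897
kovɛvo	k o v ɛ v o	888
pi	p i	879
buvu	b u v u	871
ʎefibu	ʎ e f i b u	862
bɛmeʒe	b ɛ m e ʒ e	854
subu	s u b u	846
tabi	t a b i	838
ve	v e	831
sibepu	s i b e p u	823
vuvuto	v u v u t o	816
pevu	p e v u	808
soʃu	s o ʃ u	801
vadi	v a d i	794
d͡ʒokit͡ʃa	d͡ʒ o k i t͡ʃ a	787
doso	d o s o	780
kitiko	k i t i k o	774
vu	v u	767
mɛkɛ	m ɛ k ɛ	760
fu	f u	754
tameku	t a m e k u	748
ni	n i	742
fitita	f i t i t a	736
poɲo	p o ɲ o	730
mi	m i	724
tɛdi	t ɛ d i	718
t͡ʃiɾo	t͡ʃ i ɾ o	712
bapi	b a p i	707
vono	v o n o	701
semute	s e m u t e	696
ɾupɔd͡ʒi	ɾ u p ɔ d͡ʒ i	690
lipabo	l i p a b o	685
vat͡ʃi	v a t͡ʃ i	680
paɾɔda	p a ɾ ɔ d a	675
kesu	k e s u	669
ʒuno	ʒ u n o	665
pami	p a m i	660
sisu	s i s u	655
fasine	f a s i n e	650
savuvi	s a v u v i	645
mama	m a m a	641
fe	f e	636
lɛsɔ	l ɛ s ɔ	632
ʃudo	ʃ u d o	627
poko	p o k o	623
ka	k a	618
minɛ	m i n ɛ	614
pabɔ	p a b ɔ	610
ʎɛdo	ʎ ɛ d o	606
dimu	d i m u	602
ʁegu	ʁ e g u	598
lu	l u	594
kɛza	k ɛ z a	590
dodi	d o d i	586
tepedu	t e p e d u	582
kɔsi	k ɔ s i	578
be	b e	574
ze	z e	571
vuʒo	v u ʒ o	567
tupɛ	t u p ɛ	563
beʒɔ	b e ʒ ɔ	560
fade	f a d e	556
kuse	k u s e	553
tesi	t e s i	549
ɲeda	ɲ e d a	546
vase	v a s e	543
midapa	m i d a p a	539
tɛ	t ɛ	536
sudipi	s u d i p i	533
pumaɾɔ	p u m a ɾ ɔ	530
bapisi	b a p i s i	526
zɛt͡ʃu	z ɛ t͡ʃ u	523
muɾema	m u ɾ e m a	520
duvinu	d u v i n u	517
mike	m i k e	514
mafa	m a f a	511
masi	m a s i	508
mamole	m a m o l e	505
bet͡ʃi	b e t͡ʃ i	502
soʒat͡ʃe	s o ʒ a t͡ʃ e	500
padigo	p a d i g o	497
ʃude	ʃ u d e	494
dali	d a l i	491
toso	t o s o	489
pavi	p a v i	486
vaʎa	v a ʎ a	483
piʒɔ	p i ʒ ɔ	481
d͡ʒiʃadi	d͡ʒ i ʃ a d i	478
maɾeɾi	m a ɾ e ɾ i	475
ʎu	ʎ u	473
ɲevi	ɲ e v i	470
ned͡ʒepi	n e d͡ʒ e p i	468
du	d u	465
vedɛ	v e d ɛ	463
mit͡ʃu	m i t͡ʃ u	460
dumo	d u m o	458
le	l e	456
pɔʃo	p ɔ ʃ o	453
bɔ	b ɔ	451
somesu	s o m e s u	449
d͡ʒuka	d͡ʒ u k a	446
dɛ	d ɛ	444
ʒunimu	ʒ u n i m u	442
nulibe	n u l i b e	440
ʃɛbuka	ʃ ɛ b u k a	437
tamo	t a m o	435
ninɛ	n i n ɛ	433
nuvi	n u v i	431
goɾo	g o ɾ o	429
mo	m o	427
kene	k e n e	425
pa	p a	423
sa	s a	421
nakenu	n a k e n u	419
mu	m u	417
ʁimu	ʁ i m u	415
ɲu	ɲ u	413
gomo	g o m o	411
bogo	b o g o	409
kogɛ	k o g ɛ	407
zobipu	z o b i p u	405
gotube	g o t u b e	403
do	d o	401
miɲa	m i ɲ a	399
dod͡ʒede	d o d͡ʒ e d e	398
mada	m a d a	396
bezo	b e z o	394
nɔ	n ɔ	392
t͡ʃɔpu	t͡ʃ ɔ p u	390
posopa	p o s o p a	389
ɲid͡ʒe	ɲ i d͡ʒ e	387
ʒato	ʒ a t o	385
naʁu	n a ʁ u	384
ʎi	ʎ i	382
bebo	b e b o	380
buti	b u t i	378
ʃuʎa	ʃ u ʎ a	377
dobe	d o b e	375
beti	b e t i	374
t͡ʃoloka	t͡ʃ o l o k a	372
lɔʃege	l ɔ ʃ e g e	370
bɔt͡ʃɔgo	b ɔ t͡ʃ ɔ g o	369
vikɔ	v i k ɔ	367
ɲeɾɛ	ɲ e ɾ ɛ	366
ʎonu	ʎ o n u	364
ɾido	ɾ i d o	363
ba	b a	361
nida	n i d a	360
memi	m e m i	358
viʒo	v i ʒ o	357
keɾuvo	k e ɾ u v o	355
ʃi	ʃ i	354
kuvito	k u v i t o	352
bimo	b i m o	351
bi	b i	350
nanidu	n a n i d u	348
ɾutu	ɾ u t u	347
vɛ	v ɛ	345
toʁi	t o ʁ i	344
ɾoɾa	ɾ o ɾ a	343
ʃɔda	ʃ ɔ d a	341
fusumo	f u s u m o	340
siɾe	s i ɾ e	339
no	n o	337
fepo	f e p o	336
mud͡ʒo	m u d͡ʒ o	335
tamuʎu	t a m u ʎ u	333
vaʒopo	v a ʒ o p o	332
dimido	d i m i d o	331
ɲatu	ɲ a t u	330
sosobɔ	s o s o b ɔ	328
bo	b o	327
naʃeʁo	n a ʃ e ʁ o	326
pudo	p u d o	325
tisi	t i s i	323
ʒunemu	ʒ u n e m u	322
neto	n e t o	321
zuna	z u n a	320
nemeʎo	n e m e ʎ o	319
nuka	n u k a	317
tomuɾu	t o m u ɾ u	316
soɾo	s o ɾ o	315
zeɾaɾɔ	z e ɾ a ɾ ɔ	314
vabema	v a b e m a	313
ɾuɾuno	ɾ u ɾ u n o	312
ped͡ʒe	p e d͡ʒ e	311
sudɛ	s u d ɛ	309
t͡ʃabi	t͡ʃ a b i	308
pudu	p u d u	307
niza	n i z a	306
ʃiɾo	ʃ i ɾ o	305
ɾɔ	ɾ ɔ	304
niʎud͡ʒa	n i ʎ u d͡ʒ a	303
puma	p u m a	302
ʃapo	ʃ a p o	301
pida	p i d a	300
keɾatu	k e ɾ a t u	299
ʎona	ʎ o n a	298
kifa	k i f a	297
ɾiseʁi	ɾ i s e ʁ i	296
pud͡ʒi	p u d͡ʒ i	295
boʒuva	b o ʒ u v a	294
muɲute	m u ɲ u t e	293
ɾano	ɾ a n o	292
bupopo	b u p o p o	291
ʁa	ʁ a	290
bupe	b u p e	289
ʁude	ʁ u d e	288
sape	s a p e	287
polu	p o l u	286
tita	t i t a	285
ɾevu	ɾ e v u	284
kivu	k i v u	283
ʎe	ʎ e	282
ʒobova	ʒ o b o v a	281
nigo	n i g o	280
sisa	s i s a	279
baso	b a s o	278
ʁibibi	ʁ i b i b i	277
su	s u	277
ki	k i	276
ʒiba	ʒ i b a	275
tufepu	t u f e p u	274
ɾisi	ɾ i s i	273
suve	s u v e	272
nize	n i z e	271
pokeka	p o k e k a	270
vat͡ʃiti	v a t͡ʃ i t i	270
siba	s i b a	269
d͡ʒogepa	d͡ʒ o g e p a	268
nodi	n o d i	267
kɔva	k ɔ v a	266
ʁe	ʁ e	265
muzo	m u z o	265
fusasu	f u s a s u	264
diɾa	d i ɾ a	263
detu	d e t u	262
doʃo	d o ʃ o	261
t͡ʃo	t͡ʃ o	260
bibɛ	b i b ɛ	260
popina	p o p i n a	259
tupeʒo	t u p e ʒ o	258
subo	s u b o	257
ʎoke	ʎ o k e	257
pɛkɛ	p ɛ k ɛ	256
t͡ʃibi	t͡ʃ i b i	255
nume	n u m e	254
neʎɔ	n e ʎ ɔ	254
ʒepa	ʒ e p a	253
seda	s e d a	252
vakosa	v a k o s a	251
ʃepe	ʃ e p e	251
vekat͡ʃɔ	v e k a t͡ʃ ɔ	250
fed͡ʒabe	f e d͡ʒ a b e	249
dodaku	d o d a k u	248
supi	s u p i	248
kɛtike	k ɛ t i k e	247
ɾuso	ɾ u s o	246
ne	n e	245
dadi	d a d i	245
ʎeta	ʎ e t a	244
d͡ʒoʎe	d͡ʒ o ʎ e	243
ʒuku	ʒ u k u	243
t͡ʃesu	t͡ʃ e s u	242
ʎikotu	ʎ i k o t u	241
kude	k u d e	241
ʃano	ʃ a n o	240
subido	s u b i d o	239
fasudo	f a s u d o	239
ɾu	ɾ u	238
biketa	b i k e t a	237
sopo	s o p o	237
meʎi	m e ʎ i	236
puke	p u k e	235
zisi	z i s i	235
bapipa	b a p i p a	234
viɾu	v i ɾ u	233
pobe	p o b e	233
momi	m o m i	232
ʁudo	ʁ u d o	231
pobi	p o b i	231
ʎut͡ʃidi	ʎ u t͡ʃ i d i	230
nofe	n o f e	230
ɾapini	ɾ a p i n i	229
kiva	k i v a	228
ʒonɛ	ʒ o n ɛ	228
padeɾa	p a d e ɾ a	227
t͡ʃedu	t͡ʃ e d u	227
ɾat͡ʃudɛ	ɾ a t͡ʃ u d ɛ	226
t͡ʃasu	t͡ʃ a s u	225
dɔ	d ɔ	225
sidɛ	s i d ɛ	224
ʃo	ʃ o	224
bɛpupe	b ɛ p u p e	223
kakavi	k a k a v i	222
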