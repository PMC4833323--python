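name	kind	start	end	strand	anticodon	start_codon	stop_codon
cox1	PCG	1	1824	+		GTG	TAG
trnL(NAG)	tRNA	1857	1918	+	TAG
nad1	PCG	1919	2821	+		ATC	TAA
nad2	PCG	2899	3954	+		GTG	TAA
nad4L	PCG	3997	4311	+		GTG	TAG
trnI	tRNA	4460	4523	+	GAT
trnD	tRNA	4575	4636	+	GTC
cox2	PCG	4705	6090	+		ATG	TAG
trnP	tRNA	6162	6227	+	TGG
cytb	PCG	6227	7492	+		ATG	TAG
rrnL	rRNA	7493	8964	+
atp8	PCG	8965	9117	+		ATA	TAA
nad4	PCG	9146	10480	+		ATA	TAA
trnH	tRNA	10490	10551	+	GTG
trnE	tRNA	10552	10617	+	TTC
trnS(NGA)	tRNA	10615	10679	+	TGA
atp6	PCG	10680	11531	+		ATG	TAG
nad3	PCG	11563	11997	+		ATG	TAG
nad5	PCG	12063	13787	+		GTG	TAG
nad6	PCG	13864	14385	+		ATA	TAA
trnW	tRNA	14420	14487	+	TCA
trnM	tRNA	14490	14559	+	CAT
trnV	tRNA	14630	14696	+	TAC
trnK	tRNA	14787	14856	+	TTT
trnF	tRNA	14896	14969	+	GAA
trnL(NAA)	tRNA	14977	15040	+	TAA
trnG	tRNA	15100	15163	+	TCC
trnQ	tRNA	17019	17086	+	TTG
trnR	tRNA	17212	17277	+	TCG
trnN	tRNA	17335	17400	+	GTT
trnT	tRNA	17420	17487	+	TGT
rrnS	rRNA	17488	18680	+
trnC	tRNA	18681	18747	+	GCA
trnY	tRNA	18767	18834	+	GTA
trnS(NCT)	tRNA	18873	18939	+	TCT
cox3	PCG	18940	19848	+		ATG	TAA
trnA	tRNA	19861	19933	+	TGC
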