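#genome_length=15955
name	category	start	end	strand	anticodon	start_codon	stop_codon
cox1	PCG	1	1542	+		ATA	TAA
trnL2	tRNA	1543	1605	+	TAA
cox2	PCG	1608	2297	+		ATG	TAA
trnK	tRNA	2299	2367	+	TTT
trnD	tRNA	2370	2434	+	GTC
atp8	PCG	2435	2593	+		ATG	TAG
atp6	PCG	2587	3261	+		ATG	TAA
cox3	PCG	3261	4049	+		ATG	TAA
trnG	tRNA	4056	4120	+	TCC
nad3	PCG	4121	4474	+		ATC	TAA
trnA	tRNA	4475	4535	+	TCG
trnR	tRNA	4535	4598	+	GTG
trnN	tRNA	4599	4663	+	GCT
trnS1	tRNA	4664	4730	+	TAG
trnE	tRNA	4731	4798	+	TTC
trnF	tRNA	4797	4860	-	GAA
nad5	PCG	4860	6584	-		GTG	TAA
trnH	tRNA	6585	6648	-	TAA
nad4	PCG	6649	7983	-		ATG	TAG
nad4l	PCG	7977	8276	-		ATG	TAA
trnP	tRNA	8286	8351	-	TGG
trnT	tRNA	8357	8420	+	TGT
nad6	PCG	8428	8952	+		ATT	TAA
cytb	PCG	8952	10086	+		ATG	T
trnS2	tRNA	10087	10154	+	TGA
nad1	PCG	10182	11123	-		ATG	TAG
trnL1	tRNA	11151	11216	-	GAA
rrnL	rRNA	11217	12514	-
trnV	tRNA	12515	12579	-	TAC
rrnS	rRNA	12579	13368	-
CR	CR	13369	14527	.
trnI	tRNA	14528	14594	+	GAT
trnQ	tRNA	14627	14694	-	TTG
trnM	tRNA	14700	14764	+	CAT
nad2	PCG	14765	15760	+		ATG	TAG
trnW	tRNA	15759	15824	+	TCA
trnC	tRNA	15824	15886	-	GCA
trnY	tRNA	15887	15951	-	GTA
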