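# Synthetic stand-in segment profiles for the five-lesion case (hg19
# coordinates, integer total copy number). FA3 and MalignantPT share three
# non-telomeric, non-centromeric breakpoints (chr4 ~42 Mb, chr9 ~100 Mb,
# chr16p ~30 Mb) plus private ones; BenignPT is flat.
ID	chrom	loc.start	loc.end	seg.mean
FA1	chr20	1	40000000	2
FA1	chr20	40000001	63025520	3
FA2	chr7	1	80000000	2
FA2	chr7	80000001	159138663	3
FA3	chr4	1	42000000	1
FA3	chr4	42000001	191154276	2
FA3	chr9	1	100000000	2
FA3	chr9	100000001	141213431	1
FA3	chr16	1	30000000	1
FA3	chr16	30000001	62000000	2
FA3	chr16	62000001	90354753	1
FA3	chr19	1	10000000	1
FA3	chr19	10000001	59128983	2
BenignPT	chr1	1	249250621	2
BenignPT	chr2	1	243199373	2
BenignPT	chr3	1	198022430	2
BenignPT	chr4	1	191154276	2
BenignPT	chr5	1	180915260	2
BenignPT	chr6	1	171115067	2
BenignPT	chr7	1	159138663	2
BenignPT	chr8	1	146364022	2
BenignPT	chr9	1	141213431	2
BenignPT	chr10	1	135534747	2
BenignPT	chr11	1	135006516	2
BenignPT	chr12	1	133851895	2
BenignPT	chr13	1	115169878	2
BenignPT	chr14	1	107349540	2
BenignPT	chr15	1	102531392	2
BenignPT	chr16	1	90354753	2
BenignPT	chr17	1	81195210	2
BenignPT	chr18	1	78077248	2
BenignPT	chr19	1	59128983	2
BenignPT	chr20	1	63025520	2
BenignPT	chr21	1	48129895	2
BenignPT	chr22	1	51304566	2
BenignPT	chrX	1	155270560	2
MalignantPT	chr1	1	160000000	2
MalignantPT	chr1	160000001	249250621	3
MalignantPT	chr4	1	42400000	1
MalignantPT	chr4	42400001	191154276	2
MalignantPT	chr9	1	100300000	2
MalignantPT	chr9	100300001	141213431	1
MalignantPT	chr16	1	29800000	1
MalignantPT	chr16	29800001	75000000	2
MalignantPT	chr16	75000001	90354753	1
MalignantPT	chr19	1	14000000	1
MalignantPT	chr19	14000001	59128983	2
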