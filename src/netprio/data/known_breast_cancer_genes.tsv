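# Known breast cancer genes (OMIM / Cancer Gene Census curation).
# sources: comma-separated origin databases; usable: 1 when the symbol maps
# into the reference PPI/expression universe, 0 for the four legacy loci
# without a usable mapping. Edit freely for other curations.
# symbol	ncbi_id	sources	usable
AKT1	207	omim,cgc	1
AR	367	omim	1
ATM	472	omim	1
BARD1	580	omim	1
BRCA1	672	omim,cgc	1
BRCA2	675	omim,cgc	1
RAD51D	5892	omim	0
CASP8	841	omim	1
CDH1	999	omim,cgc	1
NQO1	1728	omim	1
ESR1	2099	omim	1
HMMR	3161	omim	1
KRAS	3845	omim	1
NQO2	4835	omim	1
PHB	5245	omim	1
PIK3CA	5290	omim,cgc	1
RAD51	5888	omim	1
RAD51C	5889	omim	1
TP53	7157	omim,cgc	1
TSG101	7251	omim	1
XRCC3	7517	omim	1
RAD54L	8438	omim	1
PPM1D	8493	omim	1
RB1CC1	9821	omim	1
CHEK2	11200	omim,cgc	1
PALB2	79728	omim,cgc	1
BRIP1	83990	omim,cgc	1
BCPR	8142	omim	0
BRCATA	8068	omim	0
SLC22A18	5002	cgc	1
BRCA3	60500	omim	0
ERBB2	2064	cgc	1
ETV6	2120	cgc	1
GATA3	2625	cgc	1
MAP2K4	6416	cgc	1
BAP1	8314	cgc	1
CCND1	595	cgc	1
EP300	2033	cgc	1
PBRM1	55193	cgc	1
RB1	5925	cgc	1
NTRK3	4916	cgc	1
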