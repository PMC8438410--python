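"""Published reference numbers from the Akebia trifoliata germplasm survey.

The survey's raw 955 x 28 genotype table was never deposited, but its
printed summary panel is itself useful input: per-locus diversity values
for the 28 SSR markers, the panel means, the core/pseudo-core comparison
means, and the headline sizes.  They are provided here as plain data for
cross-checks and worked examples; nothing in the package *fits* to them.

Columns of :data:`DIVERSITY_PANEL`: Na (allele count), Ne (effective
alleles), Ho (observed heterozygosity), He (unbiased expected
heterozygosity), Nei (gene diversity), I (Shannon index), PIC.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = [
    "POPULATION_SIZE",
    "CORE_SIZE",
    "DIVERSITY_PANEL",
    "COMPARISON_MEANS",
    "IDENTITY_MARKERS",
]

#: Accessions genotyped in the survey.
POPULATION_SIZE = 955

#: Size of the published core collection.
CORE_SIZE = 164

#: Discriminating markers of the 11-character identity card, in order.
IDENTITY_MARKERS = (
    "s28", "s25", "s74", "s89", "s68", "s30", "s13", "s100", "s72", "s77", "s3",
)

_PANEL_TSV = """\
Marker	Na	Ne	Ho	He	Nei	I	PIC
s3	4.0000	2.1867	0.8331	0.5430	0.5427	0.8772	0.4518
s4	3.0000	1.2635	0.0000	0.2087	0.2085	0.3772	0.1881
s5	2.0000	1.2018	0.0000	0.1681	0.1679	0.3083	0.1538
s13	4.0000	2.4260	0.3389	0.5881	0.5878	0.9884	0.5184
s19	3.0000	1.2717	0.0597	0.2137	0.2136	0.4423	0.2029
s22	4.0000	1.9081	0.3488	0.4762	0.4759	0.8338	0.4180
s24	4.0000	1.4441	0.2630	0.3077	0.3075	0.5870	0.2857
s25	5.0000	2.8864	0.4837	0.6539	0.6535	1.1603	0.5917
s27	4.0000	1.5906	0.1328	0.3715	0.3713	0.6942	0.3412
s28	4.0000	2.8708	0.4882	0.6521	0.6517	1.1866	0.5936
s30	4.0000	2.6522	0.3899	0.6233	0.6230	1.1080	0.5553
s32	3.0000	1.3067	0.1883	0.2349	0.2347	0.4760	0.2217
s34	4.0000	1.6833	0.2664	0.4062	0.4059	0.7404	0.3665
s40	3.0000	2.0286	0.2000	0.5079	0.5071	0.8584	0.4434
s46	4.0000	1.6737	0.2225	0.4028	0.4025	0.7544	0.3686
s50	3.0000	1.5539	0.0881	0.3567	0.3565	0.5908	0.3030
s52	4.0000	1.9707	0.2440	0.4928	0.4926	0.8646	0.4415
s57	4.0000	1.6181	0.3394	0.3822	0.3820	0.6975	0.3494
s59	4.0000	1.5182	0.1046	0.3416	0.3423	0.6152	0.3037
s67	4.0000	2.0343	0.0986	0.5087	0.5084	0.8766	0.4509
s68	4.0000	2.6354	0.2705	0.6210	0.6206	1.0916	0.5578
s72	3.0000	2.2823	0.2358	0.5624	0.5619	0.9275	0.4834
s74	4.0000	2.8566	0.2374	0.6504	0.6499	1.1549	0.5879
s77	3.0000	2.3400	0.0400	0.5746	0.5726	0.9219	0.4787
s84	4.0000	1.6493	0.1595	0.3940	0.3937	0.7671	0.3654
s89	4.0000	2.6996	0.2158	0.6307	0.6296	1.0835	0.5599
s92	4.0000	1.9091	0.0346	0.4764	0.4762	0.7087	0.3712
s100	4.0000	2.1819	0.3846	0.5420	0.5417	0.9489	0.4854
Mean	3.7143	1.9873	0.2382	0.4604	0.4600	0.8086	0.4085
"""

#: Per-locus diversity panel of the original 955-accession population.
DIVERSITY_PANEL = pd.read_csv(io.StringIO(_PANEL_TSV), sep="\t", index_col="Marker")

_COMPARISON_TSV = """\
Collection	Na	Ho	Nei	PIC
Core collection	3.5000	0.2351	0.5356	0.4753
First random	3.3929	0.2333	0.4436	0.3932
Second random	3.3214	0.2374	0.4672	0.4154
Third random	3.4286	0.2399	0.4524	0.4018
"""

#: Published panel means for the core collection and three pseudo-cores.
COMPARISON_MEANS = pd.read_csv(io.StringIO(_COMPARISON_TSV), sep="\t", index_col="Collection")
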