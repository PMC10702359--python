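exposure	outcome	direction	level	method	n_snp	beta	se	or	ci_low	ci_high	pval	p_bonferroni	p_fdr	tier
AP	phylum.Proteobacteria	reverse	phylum	ivw	.	.	.	1.075	1.003	1.152	0.038	.	.	.
AP	genus.LachnospiraceaeNC2004group	reverse	genus	ivw	.	.	.	1.148	1.033	1.275	0.01	.	.	.
AP	genus.Marvinbryantia	reverse	genus	ivw	.	.	.	1.1	1.012	1.196	0.024	.	.	.
AP	genus.Holdemania	reverse	genus	ivw	.	.	.	0.914	0.839	0.997	0.043	.	.	.
AP	genus.Oscillospira	reverse	genus	ivw	.	.	.	0.919	0.847	0.998	0.045	.	.	.
CP	genus.Prevotella9	reverse	genus	ivw	.	.	.	1.067	1.018	1.117	0.006	.	.	.
CP	phylum.Firmicutes	reverse	phylum	ivw	.	.	.	0.967	0.936	0.999	0.047	.	.	.
CP	family.FamilyXIII	reverse	family	ivw	.	.	.	0.955	0.921	0.99	0.014	.	.	.
CP	genus.Coprobacter	reverse	genus	ivw	.	.	.	0.94	0.889	0.995	0.032	.	.	.
CP	genus.EubacteriumHalliiGroup	reverse	genus	ivw	.	.	.	0.952	0.918	0.987	0.008	.	.	.
CP	genus.Fusicatenibacter	reverse	genus	ivw	.	.	.	0.955	0.922	0.989	0.011	.	.	.
CP	genus.Slackia	reverse	genus	ivw	.	.	.	0.941	0.888	0.998	0.043	.	.	.
AAP	genus.Oscillibacter	reverse	genus	ivw	.	.	.	1.045	1.007	1.083	0.017	.	.	.
AAP	phylum.Firmicutes	reverse	phylum	ivw	.	.	.	0.972	0.948	0.997	0.031	.	.	.
AAP	phylum.Tenericutes	reverse	phylum	ivw	.	.	.	0.965	0.935	0.997	0.032	.	.	.
AAP	class.Clostridia	reverse	class	ivw	.	.	.	0.973	0.949	0.998	0.036	.	.	.
AAP	class.Coriobacteriia	reverse	class	ivw	.	.	.	0.974	0.949	0.999	0.046	.	.	.
AAP	class.Mollicutes	reverse	class	ivw	.	.	.	0.965	0.935	0.997	0.032	.	.	.
AAP	family.Coriobacteriaceae	reverse	family	ivw	.	.	.	0.974	0.949	0.999	0.046	.	.	.
AAP	family.Rhodospirillaceae	reverse	family	ivw	.	.	.	0.963	0.928	0.999	0.048	.	.	.
AAP	order.Clostridiales	reverse	order	ivw	.	.	.	0.973	0.949	0.998	0.036	.	.	.
AAP	order.Coriobacteriales	reverse	order	ivw	.	.	.	0.974	0.949	0.999	0.046	.	.	.
AAP	order.Mollicutes	reverse	order	ivw	.	.	.	0.962	0.93	0.995	0.024	.	.	.
AAP	genus.EubacteriumXylanophilumGroup	reverse	genus	ivw	.	.	.	0.961	0.933	0.99	0.009	.	.	.
AAP	genus.Ruminiclostridium6	reverse	genus	ivw	.	.	.	0.969	0.941	0.998	0.039	.	.	.
AAP	genus.RuminococcaceaeUCG014	reverse	genus	ivw	.	.	.	0.953	0.926	0.98	0.001	.	.	.
ACP	class.Negativicutes	reverse	class	ivw	.	.	.	0.971	0.943	0.999	0.046	.	.	.
ACP	order.Selenomonadales	reverse	order	ivw	.	.	.	0.971	0.943	0.999	0.046	.	.	.
ACP	genus.Butyrivibrio	reverse	genus	ivw	.	.	.	0.893	0.831	0.96	0.002	.	.	.
ACP	genus.Ruminiclostridium5	reverse	genus	ivw	.	.	.	0.96	0.932	0.989	0.007	.	.	.
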