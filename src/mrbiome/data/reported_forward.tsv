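exposure	outcome	direction	level	method	n_snp	beta	se	or	ci_low	ci_high	pval	p_bonferroni	p_fdr	tier
genus.Coprococcus3	AP	forward	genus	ivw	.	.	.	1.48	1.049	2.089	0.048	.	.	.
genus.EubacteriumFissicatenaGroup	AP	forward	genus	ivw	.	.	.	1.24	1.045	1.471	0.013	.	.	.
genus.Prevotella9	AP	forward	genus	ivw	.	.	.	0.82	0.68	0.989	0.038	.	.	.
genus.Ruminiclostridium6	AP	forward	genus	ivw	.	.	.	0.696	0.548	0.883	0.002	.	.	.
genus.RuminococcaceaeUCG004	AP	forward	genus	ivw	.	.	.	0.757	0.576	0.994	0.045	.	.	.
genus.Slackia	AP	forward	genus	ivw	.	.	.	0.766	0.59	0.996	0.046	.	.	.
genus.Slackia	CP	forward	genus	ivw	.	.	.	0.633	0.449	0.892	0.009	.	.	.
family.Defluviitaleaceae	CP	forward	family	ivw	.	.	.	1.408	1.053	1.883	0.02	.	.	.
genus.Barnesiella	CP	forward	genus	ivw	.	.	.	1.484	1.055	2.088	0.023	.	.	.
genus.DefluviitaleaceaeUCG011	CP	forward	genus	ivw	.	.	.	1.443	1.042	1.998	0.027	.	.	.
genus.EubacteriumXylanophilumGroup	CP	forward	genus	ivw	.	.	.	1.502	1.049	2.15	0.026	.	.	.
genus.Sellimonas	CP	forward	genus	ivw	.	.	.	1.219	1.006	1.478	0.042	.	.	.
genus.Flavonifractor	AAP	forward	genus	ivw	.	.	.	0.29	0.12	0.71	0.006	.	.	.
genus.Haemophilus	AAP	forward	genus	ivw	.	.	.	1.76	1.02	3.037	0.041	.	.	.
genus.Intestinimonas	AAP	forward	genus	ivw	.	.	.	1.724	1.017	2.924	0.043	.	.	.
genus.LachnospiraceaeUCG001	AAP	forward	genus	ivw	.	.	.	2.011	1.193	3.389	0.008	.	.	.
genus.Sellimonas	AAP	forward	genus	ivw	.	.	.	1.673	1.169	2.395	0.004	.	.	.
genus.Oscillibacter	ACP	forward	genus	ivw	.	.	.	2.179	1.057	4.449	0.034	.	.	.
class.Melainabacteria	ACP	forward	class	ivw	.	.	.	1.801	1.288	2.519	0.0005	.	.	.
order.Gastranaerophilales	ACP	forward	order	ivw	.	.	.	1.712	1.171	2.503	0.005	.	.	.
genus.Butyricimonas	ACP	forward	genus	ivw	.	.	.	1.579	1.001	2.488	0.049	.	.	.
genus.Enterorhabdus	ACP	forward	genus	ivw	.	.	.	1.764	1.073	2.902	0.025	.	.	.
genus.EubacteriumOxidoreducensGroup	ACP	forward	genus	ivw	.	.	.	1.602	1.023	2.51	0.039	.	.	.
genus.EubacteriumXylanophilumGroup	ACP	forward	genus	ivw	.	.	.	1.899	1.179	3.06	0.008	.	.	.
genus.Sellimonas	ACP	forward	genus	ivw	.	.	.	1.347	1.006	1.803	0.048	.	.	.
family.Clostridiaceae1	ACP	forward	family	ivw	.	.	.	0.563	0.342	0.928	0.024	.	.	.
genus.Slackia	ACP	forward	genus	ivw	.	.	.	0.614	0.388	0.971	0.037	.	.	.
genus.Subdoligranulum	ACP	forward	genus	ivw	.	.	.	0.561	0.339	0.928	0.024	.	.	.
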