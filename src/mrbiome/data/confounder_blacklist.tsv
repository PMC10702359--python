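rsid	confounder_trait	source
rs9000001	type 2 diabetes	curated
rs9000002	type 2 diabetes	curated
rs9000003	cholestasis	curated
rs9000004	alcohol use	curated
rs9000005	alcohol use	curated
rs9000006	gallstone disease	curated
rs9000007	serum triglycerides	curated
rs9000008	body mass index	curated
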