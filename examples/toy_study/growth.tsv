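	carbon1	carbon2	carbon3
gAa	4.606473124917991	4.240546552848437	4.546093969053547
gAb	4.831060025335318	4.724627479128772	4.547766754488579
gB1	4.599500928461661	4.46771149142932	5.499669346886181
gB2	3.906291166291674	4.3217413922100345	3.981672749858691
gB3	4.871684072920939	4.1153062324663985	4.285098742173974
gC1a	0.0	0.0	0.0
gC1b	0.0	0.0	0.0
gC2	0.0	0.0	0.0
gC3	0.0	0.0	0.0
gD	5.175961059123326	4.82431305444205	6.07185850726864
gEa	4.217357607812228	4.453624745797141	4.747292216413565
gEb	4.716259028332623	4.329031329901817	4.7550653218732695
gM1	2.0224034122444166	5.064778866508629	4.22704623274725
gM2	4.582832908317576	2.156532923537844	3.7738533155705265
gM3	4.462665888506005	3.393248928023681	1.9829305911784665
gN1	0.0	0.0	0.0
gN2	0.0	0.0	0.0
gT1	0.0	0.0	0.0
gT2	4.700060565170114	0.0	4.4987766531446685
gT3	4.134054677548477	4.372902109487172	0.0
WT	4.378092386748621	4.26603598373956	4.15611785237844
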