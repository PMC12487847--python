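t	p	lfc
r0	 1.163473212768617	0.24887790514413283	 0.6593791645099690
r1	 1.415583434924186	0.16165673465097025	 0.8126189263801293
r2	 1.793415492745552	0.07754420539031803	 1.0169994342297217
r3	 1.507553124346113	0.13649937463109080	 0.8642342917789670
r4	 2.106036149993292	0.03905591596714320	 1.1879802528660979
r5	 1.058455263265791	0.29375370886088037	 0.6030893246673151
r6	 2.730521146096454	0.00812390030746359	 1.5580731273522026
r7	 2.070508321387236	0.04236895396662148	 1.1944171236795367
r8	 1.099580037734239	0.27555872074351306	 0.6235003112545613
r9	 0.318131175794186	0.75140219996634938	 0.1831442332875755
r10	-0.533463749684245	0.59552657581589852	-0.3050441396120381
r11	 0.528026717710872	0.59927340295609322	 0.3054793443621502
r12	 2.926850032297605	0.00470954328434936	 1.6860603905080802
r13	 0.671259790386386	0.50442637744911933	 0.3874166032310578
r14	-0.743120461839455	0.46007810175447927	-0.4313313898642072
r15	 1.845298559293322	0.06953600193228880	 1.0544090873547125
r16	 1.464385856797522	0.14789385506100672	 0.8725166227801922
r17	-0.428049694297072	0.67002562209614891	-0.2512676181351031
r18	-0.582036854374350	0.56254911196798441	-0.3308209469963318
r19	 0.141084325371342	0.88823833063097712	 0.0845369307863191
r20	-0.354939644857396	0.72378040326836135	-0.2156952047412694
r21	-0.454600868122989	0.65090639642593429	-0.2735510274476816
r22	 0.266890152775890	0.79039608694406616	 0.1514492372931825
r23	-1.153535622830266	0.25290183822691170	-0.6668196071151227
r24	 0.887745782819294	0.37794077060594267	 0.5088658392593883
r25	 3.352356468237311	0.00133736891402110	 1.9179778619011529
r26	 0.224134494812097	0.82335353479962925	 0.1282378551439241
r27	-0.987747775785151	0.32692772490154842	-0.6055831980691173
r28	 0.971342590012806	0.33496756038203557	 0.5891680064871546
r29	 1.812711271346209	0.07448035122910801	 1.1365376681381834
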