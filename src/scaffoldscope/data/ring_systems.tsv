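# smiles	name	kind	chain (pipe-separated scaffold chain, Level 0 first; multi-ring units only)
c1ccccc1	benzene	mono	
c1ccncc1	pyridine	mono	
c1cncnc1	pyrimidine	mono	
c1cnccn1	pyrazine	mono	
c1cc[nH]c1	pyrrole	mono	
c1ccoc1	furan	mono	
c1ccsc1	thiophene	mono	
c1c[nH]cn1	imidazole	mono	
c1cc[nH]n1	pyrazole	mono	
c1ocnc1	oxazole	mono	
c1csc(n1)	thiazole	mono	
c1nc[nH]n1	triazole	mono	
C1CC1	cyclopropane	mono	
C1CO1	oxirane	mono	
C1CCC1	cyclobutane	mono	
C1CCCC1	cyclopentane	mono	
C1CCCCC1	cyclohexane	mono	
C1CCCCCC1	cycloheptane	mono	
C1CCOC1	tetrahydrofuran	mono	
C1CCOCC1	tetrahydropyran	mono	
C1CCNC1	pyrrolidine	mono	
C1CCNCC1	piperidine	mono	
C1CNCCN1	piperazine	mono	
C1COCCN1	morpholine	mono	
C1CCSC1	tetrahydrothiophene	mono	
O=C1CCCO1	butyrolactone	mono	
O=C1CCCC1	cyclopentanone	mono	
c1ccc2ccccc2c1	naphthalene	multi	c1ccccc1|c1ccc2ccccc2c1
c1ccc2ncccc2c1	quinoline	multi	c1ccncc1|c1ccc2ncccc2c1
c1ccc2cnccc2c1	isoquinoline	multi	c1ccncc1|c1ccc2cnccc2c1
c1ccc2[nH]ccc2c1	indole	multi	c1cc[nH]c1|c1ccc2[nH]ccc2c1
c1ccc2occc2c1	benzofuran	multi	c1ccoc1|c1ccc2occc2c1
c1ccc2sccc2c1	benzothiophene	multi	c1ccsc1|c1ccc2sccc2c1
c1ccc2[nH]cnc2c1	benzimidazole	multi	c1c[nH]cn1|c1ccc2[nH]cnc2c1
C1CCC2CCCCC2C1	decalin	multi	C1CCCCC1|C1CCC2CCCCC2C1
C1CC2CCC1C2	norbornane	multi	C1CCCC1|C1CC2CCC1C2
C1CC2CCC1CC2	bicyclo222octane	multi	C1CCCCC1|C1CC2CCC1CC2
C1CCC2(C1)CCCC2	spiro44nonane	multi	C1CCCC1|C1CCC2(C1)CCCC2
C1CCC2(CC1)CCCCC2	spiro55undecane	multi	C1CCCCC1|C1CCC2(CC1)CCCCC2
C1C2CC3CC1CC(C2)C3	adamantane	multi	C1CCCCC1|C1CC2CCCC(C1)C2|C1C2CC3CC1CC(C2)C3
c1ccc2cc3ccccc3cc2c1	anthracene	multi	c1ccccc1|c1ccc2ccccc2c1|c1ccc2cc3ccccc3cc2c1
C1Cc2ccccc2OC1	chromane	multi	C1=COCCC1|C1Cc2ccccc2OC1
C1CNc2ccccc2C1	tetrahydroquinoline	multi	C1=CNCCC1|C1CNc2ccccc2C1
C1CN2CCC1CC2	quinuclidine	multi	C1CCNCC1|C1CN2CCC1CC2
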