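compound	kegg_id	BTL 50 cm (5 °C)	BTL 50 cm (12 °C)	BTL 50 cm (-4 °C)	BTL 200 cm (5 °C)	BTL 200 cm (12 °C)	BTL 200 cm (-4 °C)	BTL 400 cm (5 °C)	BTL 400 cm (-4 °C)	MaC2A (2 °C)	MaC2A (37 °C)
Acetophenone	C07113	+	+	+	+	+	-	-	-	+	+
Benzaldehyde	C00261	+	+	+	+	+	+	+	+	+	+
Biphenyl	C06588	-	+	-	+	+	-	+	-	+	-
Butylated Hydroxytoluene	C14693	-	+	+	+	-	+	+	+	-	+
Decanal	C12307	+	+	-	+	+	-	+	+	+	+
Dodecanal	C02278	-	+	-	-	-	-	-	+	-	+
Dodecane	C08374	+	-	-	-	+	-	+	+	+	+
Hentriacontane	C08376	+	+	+	-	-	+	+	+	-	+
Methyl Alcohol	C00132	-	-	-	-	-	+	-	+	-	+
Nonanoic acid	C01601	+	+	+	-	+	-	-	-	-	+
o-Xylene	C07212	+	+	+	+	+	+	+	+	+	+
Octanoic acid	C06423	+	+	+	-	+	-	-	-	-	+
p-Xylene	C06756	-	+	-	-	+	-	-	-	+	+
Pentanoic acid	C00803	-	+	+	-	+	+	-	+	+	+
Phenol	C00146	+	+	+	+	+	-	-	+	+	-
Tridecane	C13834	+	-	-	-	+	-	+	+	+	+
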