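taxon	08a	14a	14b	20a	20b	26a	26b	38a	38b	57a	57b	85a	89a	89b	90a	93a	93b	94a	95a	95b	95c	96a	107a	108a	108b	122a	125a	126a	129a	129b	129c	129d	135a	139a	139b	142a	142b	144a	144b	155a	162a	168a	169a	172a	172b	172c	172d	172e	182a	182b	194a	205a	206a
Monodelphis_domestica	+	-	+	+	-	+	+	+	-	+	-	-	-	-	-	+	-	-	-	+	+	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	+	-	-	-	-	-	-	+	-	+	+	-	+	-	-	-
Didelphis_virginiana	+	-	+	+	-	+	+	?	?	+	-	?	-	-	-	+	-	-	?	?	?	-	-	-	-	?	-	?	-	-	-	-	-	-	-	+	-	+	-	-	-	-	-	-	+	-	+	+	-	+	-	-	-
Metachirus_nudicaudatus	+	-	+	+	-	+	+	+	-	+	-	?	-	-	?	+	-	-	-	+	+	-	-	?	?	?	-	?	-	-	-	-	-	?	?	+	-	+	-	-	-	-	-	-	+	-	+	+	-	+	?	?	-
Rhyncholestes_raphanurus	?	-	+	?	?	?	?	-	-	+	+	?	-	-	?	+	-	-	?	?	?	-	-	-	-	-	-	?	-	-	-	-	?	+	-	?	?	+	-	-	?	-	+	+	-	-	+	+	?	?	?	+	?
Caenolestes_fuliginosus	+	?	?	-	-	+	-	-	-	+	+	-	-	-	?	+	-	-	-	-	+	?	-	-	-	-	-	-	-	-	-	-	-	+	-	?	?	+	-	-	-	-	+	+	-	-	+	+	?	?	?	+	?
Dromiciops_gliroides	+	?	?	-	-	+	-	-	-	+	-	+	+	-	-	+	-	?	+	-	+	+	+	-	-	-	+	+	+	-	-	-	+	-	+	?	?	+	+	+	-	-	+	-	-	+	+	+	?	?	?	+	?
Notoryctes_typhlops	+	-	+	-	-	?	?	-	-	+	-	?	?	?	+	?	?	-	+	-	+	+	?	+	+	-	?	+	+	-	-	-	+	-	+	-	-	?	?	+	+	d	+	-	-	+	+	+	?	?	?	+	?
Phascogale_tapoatafa	?	+	+	?	?	+	-	-	+	+	-	+	?	?	+	+	-	?	+	-	+	+	+	+	+	-	+	+	+	-	-	-	+	-	+	?	?	+	+	+	?	+	+	-	-	+	+	+	?	?	?	?	?
Dasyurus_geoffroii	+	+	+	-	+	?	?	-	+	+	-	+	?	?	+	+	-	-	+	-	+	?	+	+	+	-	+	+	?	?	?	?	+	-	+	?	?	+	+	+	+	?	+	-	-	+	+	+	-	+	-	+	?
Sminthopsis_crassicaudata	?	+	+	-	+	?	?	-	+	+	-	+	?	?	+	+	-	-	?	?	?	+	+	+	+	-	+	+	+	-	-	-	+	-	+	-	-	?	?	+	+	+	+	?	?	?	?	?	-	+	-	?	?
Myrmecobius_fasciatus	+	+	+	-	+	?	?	-	+	+	-	+	+	-	?	+	-	?	?	?	?	+	+	+	+	-	+	?	+	-	-	-	?	?	?	?	?	+	+	+	+	+	?	?	?	?	?	?	?	?	?	?	?
Macrotis_lagotis	+	-	+	-	-	?	?	-	-	+	-	+	+	+	+	?	?	-	?	?	?	+	+	+	+	-	+	?	+	-	+	+	+	-	+	-	+	?	?	+	+	?	+	-	-	+	+	+	?	?	-	?	-
Perameles_gunnii	?	-	+	-	-	?	?	-	-	+	-	+	+	+	?	?	?	-	?	?	?	+	+	+	+	-	+	+	+	-	+	+	?	-	+	-	+	+	+	+	+	+	+	-	-	+	+	+	-	+	?	+	-
Isoodon_obesulus	?	-	+	-	-	+	-	-	-	+	-	+	+	+	?	?	?	-	?	?	?	?	+	+	+	-	+	+	+	-	+	+	?	-	+	-	+	+	+	+	+	?	+	-	-	+	+	+	-	+	?	?	?
Tarsipes_rostratus	+	?	?	-	-	+	-	-	-	+	-	+	+	-	+	+	+	+	+	-	+	+	+	+	-	+	+	+	+	+	-	-	+	?	?	?	?	+	+	+	+	+	+	-	-	+	+	+	-	+	?	+	+
Pseudocheirus_peregrinus	+	-	+	-	-	+	-	-	-	?	?	?	+	-	+	?	?	+	?	?	?	+	+	+	-	+	+	+	+	+	-	-	+	?	?	-	-	+	+	+	+	+	+	-	-	+	+	+	-	+	+	?	+
Trichosurus_vulpecula	+	?	?	-	-	+	-	?	?	?	?	+	+	-	+	+	+	+	?	?	?	+	?	+	-	+	?	?	+	-	-	-	+	-	+	?	?	+	+	?	?	+	+	?	?	?	?	?	-	+	+	?	?
Macropus_robustus	+	-	+	-	-	+	-	-	-	+	-	+	+	-	+	+	+	+	+	-	+	+	+	+	-	+	+	+	+	-	-	-	+	-	+	-	-	+	+	+	+	+	+	-	-	+	+	+	+	+	+	+	+
Potorous_tridactylus	+	-	+	-	-	+	-	-	-	+	-	+	+	-	?	+	+	?	?	?	?	+	?	+	-	+	+	?	?	?	?	?	+	-	+	?	?	+	+	?	?	+	?	?	?	?	?	?	+	+	?	?	?
Vombatus_ursinus	+	?	?	-	-	+	-	-	-	?	?	+	+	-	?	+	+	+	?	?	?	+	+	+	-	-	+	+	+	-	-	-	+	-	+	-	-	?	?	+	?	+	+	?	?	?	?	?	-	+	-	+	+
Homo_sapiens	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
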