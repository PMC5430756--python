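species	state
Armadillidium_assimile	OTHER
Armadillidium_depressum	ZW
Armadillidium_granulatum	ZW
Armadillidium_maculatum	ZW
Armadillidium_nasatum	XY
Armadillidium_siculorum	UNKNOWN
Armadillidium_simoni	UNKNOWN
Armadillidium_tunisiense	UNKNOWN
Armadillidium_versicolor	UNKNOWN
Armadillidium_vulgare	ZW
Armadillo_officinalis	XY
Asellus_aquaticus	XY
Chaetophiloscia_elongata	UNKNOWN
Eluma_purpurascens	ZW
Helleria_brevicornis	XY
Oniscus_asellus	ZW
Philoscia_muscorum	UNKNOWN
Porcellio_dilatatus_dilatatus	XY
Porcellio_dilatatus_petiti	ZW
Porcellio_dispar	UNKNOWN
Porcellio_laevis	ZW
Porcellio_scaber	ZW
Porcellionides_pruinosus	UNKNOWN
Trachelipus_rathkei	ZW
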