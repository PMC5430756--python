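(Cherax_quadricarinatus:450.000000,(Talitrus_saltator:400.000000,(Asellus_aquaticus:307.000000,(Helleria_brevicornis:117.000000,(Armadillo_officinalis:66.000000,((Chaetophiloscia_elongata:36.000000,(Philoscia_muscorum:15.000000,Oniscus_asellus:15.000000):21.000000):20.667000,((Eluma_purpurascens:36.167000,(Armadillidium_nasatum:25.000000,((Armadillidium_vulgare:13.889000,(Armadillidium_tunisiense:6.944000,Armadillidium_versicolor:6.944000):6.945000):6.944000,((Armadillidium_siculorum:8.333000,Armadillidium_assimile:8.333000):8.334000,(Armadillidium_granulatum:12.500000,(Armadillidium_depressum:8.333000,(Armadillidium_simoni:4.167000,Armadillidium_maculatum:4.167000):4.166000):4.167000):4.167000):4.166000):4.167000):11.167000):11.166000,(Trachelipus_rathkei:38.000000,(Porcellionides_pruinosus:35.000000,((Porcellio_scaber:17.500000,(Porcellio_dilatatus_dilatatus:8.750000,Porcellio_dilatatus_petiti:8.750000):8.750000):8.750000,(Porcellio_laevis:13.125000,Porcellio_dispar:13.125000):13.125000):8.750000):3.000000):9.333000):9.334000):9.333000):51.000000):190.000000):93.000000):50.000000);
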