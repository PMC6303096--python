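members	sex	difficult	note
Aricia artaxerxes;Aricia agestis	male	true	cannot always be separated with certainty in either sex
Boloria napaea;Boloria pales	male	true	males cannot be separated with certainty
Pieris bryoniae;Pieris napi	male	true	males cannot be separated with certainty
Pyrgus accreta;Pyrgus alveus	male	true	indistinguishable on wing pattern; genitalia differences disputed
Zygaena romeo;Zygaena osterodensis	male	true	genitalia examination necessary; some specimens remain difficult
Coenonympha gardetta;Coenonympha darwiniana	male	true	intermediates occur in contact zones
Colias hyale;Colias alfacariensis	male	true	some males difficult
Melitaea athalia;Melitaea nevadensis	male	true	intermediate genitalia along contact zone
Aricia artaxerxes;Aricia agestis	female	true	cannot always be separated with certainty in either sex
Colias alfacariensis;Colias hyale	female	true	females cannot be separated with certainty
Erebia tyndarus;Erebia arvernensis;Erebia nivalis	female	true	females cannot be separated with certainty
Hipparchia fagi;Hipparchia genava	female	true	females cannot be separated with certainty
Melitaea athalia;Melitaea nevadensis	female	true	no morphological criteria known for females
Pyrgus accreta;Pyrgus alveus;Pyrgus warrenensis	female	true	wing pattern uninformative; genitalia overlap
Zygaena romeo;Zygaena osterodensis	female	true	genitalia examination necessary; some specimens remain difficult
Coenonympha gardetta;Coenonympha darwiniana	female	true	intermediates occur in contact zones
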