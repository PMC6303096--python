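members	shares_barcodes	note
Pyrgus malvae;Pyrgus malvoides	false	para/polyphyletic, species-specific haplotypes
Adscita statices;Adscita alpina	false	para/polyphyletic, species-specific haplotypes
Plebejus argyrognomon;Plebejus idas	false	para/polyphyletic, species-specific haplotypes
Erebia manto;Erebia bubastis	false	para/polyphyletic, species-specific haplotypes
Erebia tyndarus;Erebia arvernensis;Erebia nivalis	true	mixed cluster with shared haplotypes
Erebia ligea;Erebia euryale	true	mixed cluster with shared haplotypes
Coenonympha darwiniana;Coenonympha gardetta	true	mixed cluster with shared haplotypes
Zygaena minos;Zygaena purpuralis	true	mixed cluster with shared haplotypes
Pyrgus warrenensis;Pyrgus alveus;Pyrgus accreta	true	mixed cluster with shared haplotypes
Cupido osiris;Cupido minimus	true	mixed cluster with shared haplotypes
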