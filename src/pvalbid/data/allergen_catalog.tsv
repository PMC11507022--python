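species	allergen_code	gene_based_name
Clupea harengus	Clu h 1.0101	pvalb3
Clupea harengus	Clu h 1.0201	pvalb1
Clupea harengus	Clu h 1.0301	pvalb4
Ctenopharyngodon idella	Cten i 1.0101	pvalb4
Cyprinus carpio	Cyp c 1.0101	pvalb3_(Chr.B12)
Cyprinus carpio	Cyp c 1.0201	pvalb4_(Chr.B3)
Gadus morhua	Gad m 1.0101	pvalb2.01
Gadus morhua	Gad m 1.0102	pvalb2.02
Gadus morhua	Gad m 1.0201	pvalb3.01
Gadus morhua	Gad m 1.0202	pvalb3.02
Lates calcarifer	Lat c 1.0101	pvalb3
Lates calcarifer	Lat c 1.0201	pvalb4
Lepidorhombus whiffiagonis	Lep w 1.0101	pvalb1
Pangasianodon hypophthalmus	Pan h 1.0101	pvalb4
Pangasianodon hypophthalmus	Pan h 1.0201	pvalb7
Rastrelliger kanagurta	Ras k 1.0101	pvalb4
Salmo salar	Sal s 1.0101	pvalb4_(Chr.3)
Sardinops sagax	Sar sa 1.0101	pvalb4
Scomber scombrus	Sco s 1.0101	pvalb4
Sebastes marinus	Seb m 1.0101	pvalb3
Sebastes marinus	Seb m 1.0201	pvalb4
Thunnus albacares	Thu a 1.0101	pvalb3
Xiphias gladius	Xip g 1.0101	pvalb4
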