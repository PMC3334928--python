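# plant_taxon	order
# Editable species- or genus-level lookup mapping plant taxa to APG orders.
# Species rows ("Genus epithet") take precedence over genus rows ("Genus").
Malus domestica	Rosales
Prunus persica	Rosales
Rosa	Rosales
Rubus	Rosales
Ulmus	Rosales
Quercus	Fagales
Betula	Fagales
Juglans	Fagales
Pinus	Pinales
Picea	Pinales
Abies	Pinales
Salix	Malpighiales
Populus	Malpighiales
Euphorbia	Malpighiales
Acer	Sapindales
Citrus	Sapindales
Rhus	Sapindales
Eucalyptus	Myrtales
Epilobium	Myrtales
Trifolium	Fabales
Acacia	Fabales
Lupinus	Fabales
Medicago	Fabales
Solanum	Solanales
Ipomoea	Solanales
Nicotiana	Solanales
Fraxinus	Lamiales
Plantago	Lamiales
Artemisia	Asterales
Solidago	Asterales
Helianthus	Asterales
Vaccinium	Ericales
Rhododendron	Ericales
Camellia	Ericales
Zea	Poales
Poa	Poales
Gossypium	Malvales
Tilia	Malvales
Vitis	Vitales
Daucus	Apiales
Coffea	Gentianales
Beta	Caryophyllales
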