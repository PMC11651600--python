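Barbadori Castellani
Barbadori Ginori
Barbadori Medici
Barbadori Peruzzi
Bischeri Guadagni
Bischeri Lamberteschi
Bischeri Peruzzi
Castellani Lamberteschi
Castellani Peruzzi
Ginori Medici
Guadagni Lamberteschi
Lamberteschi Peruzzi
Medici Pazzi
Medici Salviati
Medici Tornabuoni
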