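Acciaiuoli Medici
Albizzi Ginori
Albizzi Guadagni
Bischeri Guadagni
Castellani Barbadori
Castellani Peruzzi
Castellani Strozzi
Guadagni Lamberteschi
Medici Albizzi
Medici Barbadori
Medici Ridolfi
Medici Salviati
Medici Tornabuoni
Peruzzi Bischeri
Peruzzi Strozzi
Ridolfi Tornabuoni
Salviati Pazzi
Strozzi Bischeri
Strozzi Ridolfi
Tornabuoni Guadagni
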