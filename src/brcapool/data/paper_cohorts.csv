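label,n_tested,n_positive
Robinson 2015,150,19
Mateo 2015,49,8
Mota 2020,64,6
Tukachinsky 2021,837,71
Martinez Chanza 2021,141,14
Uemura 2022,143,19
Barroso 2024,42,0
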