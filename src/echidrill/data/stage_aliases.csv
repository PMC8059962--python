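alias,canonical
Maestrichtian,Maastrichtian
Tarantian,Upper Pleistocene
Late Pleistocene,Upper Pleistocene
Ionian,Chibanian
Middle Pleistocene,Chibanian
Early Pleistocene,Calabrian
Lower Pleistocene,Calabrian
Recent,Holocene
Tyrrhenian,Upper Pleistocene
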