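name,epoch,older_ma,younger_ma
Rancholabrean,Pleistocene,0.25,0.011
Irvingtonian II,Pliocene,0.85,0.25
Irvingtonian I,Pliocene,1.72,0.85
Blancan V,Pliocene,2.5,1.72
Blancan III,Pliocene,4.1,2.5
Blancan I,Pliocene,4.9,4.1
Early late Hemphillian,Miocene,6.7,5.9
Late early Hemphillian,Miocene,7.5,6.7
Early early Hemphillian,Miocene,9,7.5
Clarendonian,Miocene,12.5,9
Late Barstovian,Miocene,14.8,12.5
Early Barstovian,Miocene,15.9,14.8
Late Hemingfordian,Miocene,17.5,15.9
Early Hemingfordian,Miocene,18.8,17.5
Late late Arikareean,Miocene,19.5,18.8
Early late Arikareean,Oligocene/Miocene,23.8,19.5
Late early Arikareean,Oligocene,27.9,23.8
Early early Arikareean,Oligocene,30,27.9
Late Orellan,Oligocene,33.1,32
Early Orellan,Oligocene,33.7,33.1
Middle Chadronian,Eocene,35.7,34.7
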