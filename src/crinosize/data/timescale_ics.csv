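stage,base_ma,top_ma
Tremadocian,485.4,477.7
Floian,477.7,470.0
Dapingian,470.0,467.3
Darriwilian,467.3,458.4
Sandbian,458.4,453.0
Katian,453.0,445.2
Hirnantian,445.2,443.8
Rhuddanian,443.8,440.8
Aeronian,440.8,438.5
Telychian,438.5,433.4
Sheinwoodian,433.4,430.5
Homerian,430.5,427.4
Gorstian,427.4,425.6
Ludfordian,425.6,423.0
Pridoli,423.0,419.2
Lochkovian,419.2,410.8
Pragian,410.8,407.6
Emsian,407.6,393.3
Eifelian,393.3,387.7
Givetian,387.7,382.7
Frasnian,382.7,372.2
Famennian,372.2,358.9
Tournaisian,358.9,346.7
Visean,346.7,330.9
Serpukhovian,330.9,323.2
Bashkirian,323.2,315.2
Moscovian,315.2,307.0
Kasimovian,307.0,303.7
Gzhelian,303.7,298.9
Asselian,298.9,295.0
Sakmarian,295.0,290.1
Artinskian,290.1,283.5
Kungurian,283.5,273.01
Roadian,273.01,266.9
Wordian,266.9,264.28
Capitanian,264.28,259.51
Wuchiapingian,259.51,254.14
Changhsingian,254.14,251.902
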