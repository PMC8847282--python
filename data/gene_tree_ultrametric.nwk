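((((sp2_3:0.00132094490061744,sp2_4:0.00132094490061744):0.00389644636330451,((sp2_8:0.00088273207609373,(sp2_2:0.0008106685743331,sp2_6:0.0008106685743331):7.206350176063e-05):0.00098953004501338,(sp2_7:0.00098063283649194,(sp2_1:7.967192433319e-05,sp2_5:7.967192433319e-05):0.00090096091215875):0.00089162928461517):0.00334512914281484):1.0095422712393487,(sp1_3:0.00859316821684433,(sp1_1:0.00386523714148283,((sp1_8:0.0014883624982055,(sp1_4:5.873569182722e-05,sp1_5:5.873569182722e-05):0.00142962680637828):0.00119969534549092,(sp1_2:0.00213926636345257,(sp1_6:0.00036247753521398,sp1_7:0.00036247753521398):0.00177678882823859):0.00054879148024385):0.00117717929778641):0.00472793107536149):1.0061664942864263):0.500034950804706,((((sp5_4:0.00013280210704921,sp5_6:0.00013280210704921):0.001644402118096,(sp5_7:0.00093258027271046,(sp5_2:0.0002332113849354,sp5_8:0.0002332113849354):0.00069936888777506):0.00084462395243476):0.01722812181582338,(sp5_3:0.0048817008336843,(sp5_1:0.00131748478404946,sp5_5:0.00131748478404946):0.00356421604963484):0.0141236252072843):1.363439771480736,((sp4_6:0.00659923379322641,((sp4_5:0.00040770241902868,sp4_7:0.00040770241902868):0.00546611953724846,(sp4_2:0.0006058076137819,(sp4_1:0.00054920807141502,(sp4_8:0.0004377272368409,(sp4_3:3.082775270031e-05,sp4_4:3.082775270031e-05):0.00040689948414058):0.00011148083457412):5.659954236688e-05):0.00526801434249524):0.00072541183694926):1.1122174144876715,((((sp3_1:0.00024145073651532,sp3_2:0.00024145073651532):0.00060620329173444,(sp3_4:0.00070152952831,sp3_5:0.00070152952831):0.00014612449993976):0.00103713898676112,(sp3_6:0.00135998778672389,sp3_7:0.00135998778672389):0.00052480522828699):0.00927230697490151,(sp3_3:0.00490079520214304,sp3_8:0.00490079520214304):0.00625630478776935):1.1076595482909855):0.26362844924080675):0.13234951578627197);
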