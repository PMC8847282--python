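((((sp2_3:6.6047245030872e-05,sp2_4:6.6047245030872e-05):0.00019482231816522552,((sp2_8:4.41366038046865e-05,(sp2_2:4.0533428716655004e-05,sp2_6:4.0533428716655004e-05):3.6031750880315002e-06):4.9476502250669e-05,(sp2_7:4.9031641824596995e-05,(sp2_1:3.9835962166595e-06,sp2_5:3.9835962166595e-06):4.5048045607937504e-05):4.45814642307585e-05):0.000167256457140742):0.050477113561967435,(sp1_3:0.00042965841084221656,(sp1_1:0.0001932618570741415,((sp1_8:7.441812491027501e-05,(sp1_4:2.9367845913610005e-06,sp1_5:2.9367845913610005e-06):7.1481340318914e-05):5.9984767274545996e-05,(sp1_2:0.0001069633181726285,(sp1_6:1.8123876760699e-05,sp1_7:1.8123876760699e-05):8.88394414119295e-05):2.74395740121925e-05):5.8858964889320506e-05):0.00023639655376807452):0.05030832471432132):0.0250017475402353,((((sp5_4:6.640105352460501e-06,sp5_6:6.640105352460501e-06):8.222010590480001e-05,(sp5_7:4.6629013635523005e-05,(sp5_2:1.1660569246770001e-05,sp5_8:1.1660569246770001e-05):3.4968444388753e-05):4.223119762173801e-05):0.0008614060907911691,(sp5_3:0.000244085041684215,(sp5_1:6.5874239202473e-05,sp5_5:6.5874239202473e-05):0.00017821080248174202):0.0007061812603642151):0.06817198857403681,((sp4_6:0.00032996168966132055,((sp4_5:2.0385120951434e-05,sp4_7:2.0385120951434e-05):0.00027330597686242304,(sp4_2:3.0290380689095e-05,(sp4_1:2.7460403570751e-05,(sp4_8:2.1886361842045e-05,(sp4_3:1.5413876350155002e-06,sp4_4:1.5413876350155002e-06):2.0344974207029003e-05):5.574041728706e-06):2.829977118344e-06):0.00026340071712476203):3.6270591847463e-05):0.05561087072438358,((((sp3_1:1.2072536825766e-05,sp3_2:1.2072536825766e-05):3.0310164586722004e-05,(sp3_4:3.50764764155e-05,sp3_5:3.50764764155e-05):7.3062249969880005e-06):5.1856949338056e-05,(sp3_6:6.799938933619451e-05,sp3_7:6.799938933619451e-05):2.6240261414349504e-05):0.0004636153487450755,(sp3_3:0.000245039760107152,sp3_8:0.000245039760107152):0.0003128152393884675):0.05538297741454928):0.013181422462040338):0.006617475789313598);
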