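-1.0038974016e-01,5.6018001238e-02,2.4612845237e-01,2.9687841490e-01,1.8076026737e-01,1.5232454598e-02,-7.8798312089e-02,-1.5837302721e-01,1.2005189222e-02,2.2625504037e-01,2.7262073624e-01,1.2626485934e-01,-5.8528355256e-02,-1.4146848601e-01,-1.9267215197e-01,-6.7388047107e-02,9.2139397926e-02,1.0562004023e-01,-2.7183990643e-02,-1.5180873121e-01,-1.6977864297e-01,-1.7218833592e-01,-1.2479041882e-01,-6.9183762575e-02,-9.9553185189e-02,-1.7671353909e-01,-1.9141389687e-01,-1.3184811205e-01,-7.8192029754e-02,-8.7921765464e-02,-1.2051250022e-01,-1.8076152991e-01,-1.9395713899e-01,-1.0840625902e-01,-7.0799096499e-03,5.7396066218e-02,4.1249046018e-02,-2.6107522251e-02,-8.2005427485e-02,-4.7069549215e-02,7.6546347604e-02,1.6183314788e-01,1.5168549134e-01,1.5126413246e-01,1.0153698670e-01,7.1461957277e-02,1.1922990669e-01,2.1926200494e-01,2.6270642617e-01
1.5182444599e-01,1.8521429685e-01,1.4953462738e-01,4.8055880630e-02,-9.6934932378e-02,-2.3205994708e-01,-2.7036826327e-01,2.0376781309e-02,4.8430072833e-02,7.1555244799e-02,7.0150006243e-02,8.3412115525e-03,-9.9214221497e-02,-1.6184764181e-01,-1.6450669382e-01,-1.6290987444e-01,-6.5190288818e-02,7.2615434381e-02,1.5578131727e-01,1.2975223807e-01,4.6826685640e-02,-2.2850684891e-01,-2.5297339568e-01,-1.4159265245e-01,4.9846974124e-02,2.1586981588e-01,2.5611047256e-01,1.7578090478e-01,-1.0032277851e-01,-1.3356243488e-01,-9.5995171729e-02,1.2870139973e-02,1.2651445246e-01,1.5938278773e-01,1.0852948336e-01,1.0674307581e-01,8.6023693096e-02,2.6689035896e-02,-1.7432439530e-02,-4.5974888564e-02,-7.0966517259e-02,-8.1483593863e-02,2.2185580970e-01,2.1278210273e-01,1.0913333214e-01,-2.8541585941e-02,-1.5177565663e-01,-2.1781991869e-01,-2.0661057743e-01
-3.9435842815e-01,-2.5879597032e-01,-4.3340848975e-02,5.6947766985e-02,6.9562481904e-03,-9.1771597116e-02,-1.4419130644e-01,-3.1210402257e-01,-1.0987976293e-01,1.5123676425e-01,2.3193436933e-01,1.1982175815e-01,-3.3638295018e-02,-1.1254775006e-01,-1.4664536983e-01,8.1092660641e-02,3.0409056111e-01,3.1860639208e-01,1.5990146757e-01,1.7524116580e-03,-6.8192367236e-02,-2.1306484284e-02,1.6340189621e-01,2.8774504655e-01,2.2689388371e-01,6.8149505190e-02,-2.8885197391e-02,-4.4111990400e-02,1.6986188250e-02,1.2066521336e-01,1.4223463438e-01,3.9642742130e-02,-6.7015328721e-02,-6.7006404748e-02,-1.9433278422e-02,2.7136900953e-04,3.5400294436e-02,-1.2735577889e-03,-9.1846891894e-02,-1.2441896916e-01,-5.3505348359e-02,2.1103069267e-02,-2.5556664023e-02,-2.5331764204e-02,-6.8192935147e-02,-1.1910773296e-01,-1.0410911071e-01,-2.0622542511e-02,4.2355676896e-02
3.6345950192e-02,-3.0500034322e-02,7.0672821378e-03,1.7172045844e-01,2.6593527300e-01,1.4490232508e-01,-4.9502859337e-02,1.6946347147e-03,-1.6033003087e-01,-1.8059307341e-01,1.0206963967e-02,1.4647159725e-01,9.6263082371e-03,-2.0340633088e-01,5.0989866613e-02,-1.7410039369e-01,-2.6665559988e-01,-8.5255534939e-02,6.8405055730e-02,-6.8891427386e-02,-2.8397260620e-01,1.8253562013e-01,-2.9962407122e-02,-1.5177101141e-01,1.5090626396e-02,1.8104520498e-01,4.5906023647e-02,-1.9338796150e-01,2.5941709560e-01,6.7716789915e-02,-5.9185293156e-02,9.8466343359e-02,2.8197364685e-01,1.7679485508e-01,-5.6664822118e-02,1.8304601060e-01,-1.6169370356e-02,-1.4730016074e-01,-1.1280836389e-02,1.7971604776e-01,1.4661279847e-01,-1.5918196783e-02,4.8504392545e-02,-1.3416950308e-01,-2.5016097805e-01,-1.6349353202e-01,-1.0810695599e-02,1.6502119083e-02,-5.3210630545e-02
1.3011672718e-01,1.3221112417e-01,7.3678912199e-02,-3.2033502526e-02,-1.5139431666e-01,-2.3546034937e-01,-2.4508135336e-01,1.5581226357e-01,1.7519763973e-01,1.2418531685e-01,1.6205352608e-02,-1.1405086263e-01,-2.1103373111e-01,-2.2884226000e-01,1.2231011043e-01,1.5909427820e-01,1.4185635307e-01,7.5942417451e-02,-1.9267514692e-02,-1.0110635328e-01,-1.3192493445e-01,2.2042349037e-02,6.6135395553e-02,9.8598225567e-02,1.0471520658e-01,8.0330116465e-02,3.8430430968e-02,-1.5581102547e-03,-1.1843474309e-01,-8.4440251696e-02,-7.3688402546e-03,7.6600532846e-02,1.3348749357e-01,1.4554588018e-01,1.1073368529e-01,-2.4015482571e-01,-2.2398456345e-01,-1.2404188206e-01,8.5658888497e-03,1.2513386630e-01,1.8286703617e-01,1.6449410619e-01,-2.7593955144e-01,-2.6970952710e-01,-1.8003840667e-01,-4.7331187272e-02,7.9399601263e-02,1.5085811978e-01,1.4864863702e-01
-8.8786993337e-02,-6.1707207837e-02,-1.4384482032e-02,-1.9628221358e-02,-7.6972918147e-02,-1.2299685544e-01,-1.0778562930e-01,-3.9710224611e-02,-1.7155283468e-03,4.2800503255e-02,2.7828063023e-02,-2.8450104274e-02,-5.6985273072e-02,-3.4790569961e-02,5.3433246438e-02,6.7647026543e-02,5.8240199026e-02,2.2478882257e-02,4.6888538397e-03,4.7014742988e-02,1.0143394261e-01,1.4177762738e-01,9.2051228785e-02,-1.6822436767e-02,-9.4026536080e-02,-5.1357332702e-02,1.0196711780e-01,2.2109317532e-01,2.0367455783e-01,7.8235524560e-02,-1.3662601656e-01,-2.6072960352e-01,-1.6616235549e-01,8.7523203967e-02,2.7221165610e-01,2.3161004839e-01,6.9244055241e-02,-1.9561278839e-01,-3.4337625702e-01,-2.3067228963e-01,5.6688191172e-02,2.6370808385e-01,2.1172146934e-01,7.0832082617e-02,-1.5638277032e-01,-2.8267048012e-01,-1.9209816164e-01,3.9845382236e-02,2.1270217140e-01
3.2960098809e-01,2.6633965499e-01,1.6522254386e-01,1.1533990321e-01,8.3111799344e-02,6.7709247328e-03,-7.5556924572e-02,2.8963571786e-01,1.7355015554e-01,4.4790486185e-02,1.7539496458e-02,1.9695014819e-02,-5.4054699897e-02,-1.4594083664e-01,2.1547955920e-01,6.7232295417e-02,-5.7315191604e-02,-4.4536113157e-02,-7.6221309047e-03,-8.1728730100e-02,-1.8880670849e-01,1.8100772266e-01,4.7994140577e-02,-4.6342742350e-02,-5.6498817118e-03,3.8030424990e-02,-5.7691455408e-02,-1.9307957599e-01,1.7393831280e-01,7.1606172171e-02,8.6445546343e-04,3.6689228480e-02,5.1506932868e-02,-7.4663225077e-02,-2.1959721502e-01,1.4306081766e-01,5.5425473442e-02,-1.5026633734e-02,-1.5211040256e-02,-4.4470859141e-02,-1.7522189990e-01,-2.8712989741e-01,8.6362479217e-02,9.3013795874e-03,-6.3076523983e-02,-1.0071531361e-01,-1.5770550341e-01,-2.5870146287e-01,-3.2025151438e-01
-8.0073734838e-02,-8.3961476016e-02,-8.7994579054e-02,-1.3017213422e-01,-2.0858741351e-01,-2.7660288835e-01,-2.8043324683e-01,-6.3887842359e-02,-6.1333036865e-02,-5.7467828711e-02,-9.5814128272e-02,-1.7847730162e-01,-2.5374795638e-01,-2.6388609925e-01,-1.5385554365e-02,-1.4313623652e-02,-1.5281790771e-02,-4.7874937588e-02,-1.1103941443e-01,-1.6518670414e-01,-1.7700777012e-01,6.7179682455e-02,5.8381698201e-02,3.4337918980e-02,-4.2662162798e-03,-4.2157507405e-02,-6.2588494760e-02,-6.6977455637e-02,1.6975139182e-01,1.5315198491e-01,9.7875707724e-02,4.1093873509e-02,1.5180726806e-02,1.9636334805e-02,2.2389846411e-02,2.5597185552e-01,2.4252453384e-01,1.6755076817e-01,9.3121263198e-02,6.4366230475e-02,7.4750321062e-02,7.7151725700e-02,2.7967592444e-01,2.7271319741e-01,2.0521602350e-01,1.3369116291e-01,1.0023933946e-01,1.0105469487e-01,9.7512929232e-02
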