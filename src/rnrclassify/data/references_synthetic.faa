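>BETA_IA_SYN E. coli-like Ia beta (synthetic)
TTHECDSDEMVVKHAWRSWCHFIMNHYMETYSVTIPKISRYATELNYWGDIGPYTSNFLW
FMTARGQCAPVPARHNSPEKKMDADISTKHIQIAVRVDETGWCPYFHIKYPLHHSEWHHI
YYFHKNPGDKDQNLLYFRYCCGHAERYVNRHNHDCIGSVQNYDLHRFPRMQECKWNSDPN
PHTMVWHTCHLSTKFRQCAMAYQKEMLMNQFQYEKQYLAQYCESYAGGEECQYFHPSDES
YHFGCIFYQSSVHTANQDNAGHCWSQHMCWVIQIEPTDECECIWSSQIMVKKYRLKMNQP
CIYCGQVLAMALVVIKQIWYAHDCERNVKDGYMGRRPVTNNLAQGIIYMFWWGFLYALYG
VRHDMNNPTEYEKPME
>BETA_IB_SYN S. typhimurium-like Ib beta (synthetic)
WCHFIMNHYMETYSVTITMISRYAGELNYSGTIGPYTSNNLWFMTARGGCGPVPAVHNSQ
EKKMDADISTKHIQIFVRVRETPWCPYFSIKYCLHHMEWHHIYYFHKNPHDKNQNLLYGR
TCCGHAERYVNRHNHVNSGSVMMYDLHRFMRMQVCKWEMLMNQFQFPKQYLAQYCTNYAG
GEECQLFHPSDESYHFGCSFYQSSVHTANQDNAGHCWSQNMCWVFQIEPVDECECRWSSQ
IMVKKYRAKMNQVCIYCIQVLAVALNVIKQIWYAHDCERAVKDGYMGRRPVTNRLAQGCI
YSFNWGFLYALAGVRHDMNNPCEYEKPMNL
>BETA_IC_SYN C. trachomatis-like Ic beta (synthetic)
HPPNTTHECDSDEMHVKYAYRSWCHMIMNHYMETYSHTITMESCYAGELNCWGDIGPDTS
NFLWFMTARGQTAPVPARHNSQEKKMDAEISTKHIQIFVRVRETGWHPYFHIKYPLHHEE
WHHIYFFHKNFGDKNQCLLYGGTCCGHAERYVNMWKGDCIGSVMNYDLVRFPRMEECKWN
SVVIPETLVWVTEMLMNDFQFPLQYLYQYCTSWAIGEECQYSHPSDESYHFGCSFYQSSV
HTANQDNAGHCWSQNMCWVIQIEPTDECECIWSSEIMEKKYRGKMNQVCIYCGQVLAPAL
VQIKQIQYAHDCERNVYDGYMGKRPVKNNLAQDCIYMFNTGFLYGL
>BETA_ID_SYN F. johnsoniae-like Id beta (synthetic)
QCHFIMNHYMETHSVTITMISRHAGELAYWGDIGPYTSNFLWFMTARGQCAPVPARHNSQ
EKKMDAEISTKINQIFVRVPETGWCPYFHIKYPLHCEWHHIYYFHKNPGEHNQNLLYGRT
CCGHMEDYVNEINHDRIGSGMNYDLHRFPRMIGCKWNSDEMLMNQRQFPKQYLLIYCTVY
AGGEECQYFQPSYDESYHFGCSFYQSSVHTANQDNAGHIWSQNMCWVILIEPTDECEHIW
SSQIMVKKYRAKMNQVCIYCGQVLAPALVVIKNIWYDHDCESNPKDGYMGRRPVTMNLAQ
GCIYMFNWGFWYALYGVRHD
>BETA_IE_SYN A. urinae-like Ie beta (synthetic)
GTHECDRDEMVVKHAWRSWTHFRMNHYMETYSVSITMIRRVAGELNYWGDIGPYPSNFLW
YMTARGQCAPVPARHNSQEKKMDADISTKHIQIFVRVREHGWCPYFHIKYFLHHMVWHHI
YYFHKNPGDKNQNKLYGRTCCGHAERYVNRNNEDCAGSVMQHDLHRFPRMQECKWPMLMN
QFQFPKQYLAQYCTSYAGGEECQYFHPSDKSYHFGCSFYQSSVHTANQDNAGHCWTPNMC
WKIEIEPTDECECDWSSQIMVKKYRAKMNQVCIYCKQVLAPALVVIKQIWYAHDCERNVK
DGYMGREIVTNNLAQLWWYMFNWGFLGALY
>ALPHA_IA_SYN Class I alpha Ia representative (synthetic)
GEINKKVRMHYNIHWHIGKPHSSAKGTRWMQWLPRNQDNHTDRVCRTVSCGCSVEYQQHF
WGNDNHTFVNHWSHTQRECFRSKEVPSTTSGYEEVVVTTTHIYIHSPTPYSKLHWAACFE
SHSDSKQWFEMIPMEMVTWARNARVKPWDWMIVSRKRFEPFCITAKFKHRSENLNDIIFH
RNPHTAFRWHLCRNPFYARIHCTYLYMVWCMVKFSSGLFGENFWCGQYFYRCMNLGMANW
YTFCIWNSLRAIGDLTTQVLVVGHEWEDIMFPSYNMPVNRKFHSAVEKDPQCFMAHCQKF
GTTCQVVGNLFGRNRAMGVKRNPSNRSHHDINNEISQGTEGYFKYCELPISHYIEIPWIC
HCSHAFVQIHTIWPSWCFSAPYFYRTVNGYAAEIGCKYLMNDYALWSHAEPSERNKKWYM
LNCWCWPLFLQEKMPNNCCNEPHEYVMMWSGSMNRTCLMYCCYLTAYLPVNMFNDSWEHD
CPGGHQTQNPTMQTKKESHVLAVAVCKADCWWRNRTKVMMQDHSWNLVHWACTHMSLCMP
DEVFECGGWHPTNFCPFEHDTKKWHVVTKACCEHSDIAAYMRNVRPFAWVGHNEGCGNMH
NTISDPWWIFNGCCPMHNVMQIEYSLPKSKFSGHWGCYAPLVMCEGPHCVALTGGVNLNM
KWYYAEIGTKPESFFLWNRDERQKWWDWDFRNNIEFKQNRTFWTENMAGFLMFPFVILCG
RQTGDDWGWYYYYQEDYCQTDPSPN
>ALPHA_IB_SYN Class I alpha Ib representative (synthetic)
GEINIKPRMHYNIHWHIGSMHSSALGTRWVQWLPRNQDNHTDRACRTVSKGCEVEYQQHF
YGNINHTFVNHWSHTKRECYRLKEVPSTTNGYEEVVVTTTQQIIHSPTPYSKLHWAICFE
SHSDSKFWFEMIPMEMVTKARNARVKPWPWEIVSRKRFEPFCITAAFFHRSLNLNDIGWH
RSPHTAMRWHLCRTKPYARGQIVYLYMVWCTVKFSDVLFGSNFWCGQYTYRCWNLAYANW
YTFSIWNVLRAIGQLTTQVLVCGHEWEIIMFESYNMPVNRKAHSAVEKDPQCFMAHDQEF
GTTCQVVRNLFWNNRAMGVAVNPSNRYHLDIHDEISQITEMAFKYCELPISHYIETPWIC
HCSFAFIQIHYIWPSWCFSAPYFQRTVNTYAAEIGQTYLMNRYDLWSHAEESNRNVKWYM
LNCWCWPRVLQEKMPNNCCNEPHEYVMMWSGSMNRTDLMYCCYLTAMLPVNMFNDSPEHD
CQNGHQTDNITMQTRKESHPLAVAVQKSDIWWRNNTKVMMFWHSRNVVHWCWCHMSLCMP
DEKFERGGWHPTNFCGFEHDTKKFHVVTTACCCHIDIHGFMMNVRPFAWVGHNGGAGNMH
NFISDPWWIFVGCCPCHNVMQIEYSLPKSKFSGHWGCPAPLVMCEFPHCVALTLGVNLNM
KWYTAEIGTKPESQSLWNRDERPKWWNWDFCSNICFLKCRTAWTENMDGFLMFPFLILCG
RSTGDWWGWYYYYQEDYCQTVPSPN
>ALPHA_IC_SYN Class I alpha Ic representative (synthetic)
GEINWKVRMHYNIHWHIGKMHSSAKGTRWVQWLPRNQDNHTDSVCRTVSSGCPVEYQQHF
FGNDNHTFVNSWSHTKRECWRLKEVCSTTSGYEEVVVTTTHIIIHSPTPYSKIHWGICFE
SHSDFKWWFEMIPMEMNTKLRNARIKPWNNMIVSRKRFEPFCITAAFFHRSLNENDIAFH
RSPHTAFRWHLCRNPPYARIHIVYMYMVWHMAKFSDGLFGSNFWCGQYTYRCMNFAMANW
YTFSGWNVLRMINDLYTQVLRYGHEWEDIGFESYNMPVNRKAHSAVEKDPQCFMAHHIEF
GTTCQVVRNLFWRNRAMGVKRNPSNRYHLDIHNEISQITEGYFKSCELPISHYIETPWQC
HCGFAFVQIHYIWPSWCFDAPYFYRTVNHYAAEIGQKYLMASYDNWSHAEPSERNVKMYM
LWCWCWPRHLWAKMPNNCCNEPHEYVWMWSGSKNVTDLMYCCYLTAMLPVNMFNDPWEHD
CPNGHQHDNPTMQTKKESHVLAVAVQTSDCWWRNRTKVMMFDHSWNVHHPCCCHMSLCMP
DEVFECGGWHPTNFCSFEHDTKKFHVVTKACCEHSDIAAFMRGVRPFAWVGPNGGCGNMH
NFISDPWWLFVGCCPMHNVMQIEYSLPKHKFSGHWGCPAPLVMCEGPHMVALTLGVNLNM
QWYYAEIGTKPESFSLWNRDEIQKWWNWDFRNNICFKQNFTDWTENMAGFLPFPFLILCV
RQTGDDWGWYYYYQEDYCQTVPSPN
>ALPHA_ID_SYN Class I alpha Id representative (synthetic)
GEINIKVRPHYNIHYQIGKMHDSAKGTRWVQGLPRNQDCHTDRVCRTVSKGCPVEYQQHF
YGNDNHLFVNHWSHTKRECFVLKEVPSTTSGYEEVNVETTGIIIHSPRPTSKLEWAICFE
SHSDSKQWFEMIPMEMVTKARNARVKPWNNMIVSRKRFEPFCITAAFFPWSSNLNDIGFH
FSPHTANRWHLCRNPPYARIHIVYLYAVSCMVKHSDGLFGSNFWCGQYTYRMMNLAAANW
YTFSIWNVLRAIGDLTTQVLRYGHEWEDIMFESYNMIVNRKAHSAVEKDPQCFMAHHQCF
GTNCQVVRRAFWRYRAMGVKRNGKGRYHLDIHNEFSQITEMYFKYCEEPLSHYIETPWIC
HCSFAFHQIHYEWPRQCFSAPYMYRYVNGYAAEIGQKYLMGDYDLWSHAEPSERNVPWYM
LNCWCWPRHLNEKMPNNCCNEPHEYVMMWSGVMNRTHAMYCCYLTAMLPVNMFNDDWEHN
CPNGHQTDNPTEQTKKESHVLAVAVQDSGCWWRNRTKVMMFDHSWNMVHWCCCHMSLCMP
DEWFECGGWHPTNFEDFDHDTKKFHVVTWECNEHSDIAAFMRNVRPFAWVGHNGGCGFMH
NFISDPWSIFVGCCPMFNVMAIEYSLPKSKFSGINGPPAPLFMCEGPHCVALALGVNLNM
VWYYAEIGTKPESFSLWNRDERQKWWNGDFYNNICFKQNRTDWTENMAGFLMFPFLILCG
RQTGDDWGWYYYYQEDHCQTVPSPN
>ALPHA_IE_SYN Class I alpha Ie representative (synthetic)
GEINIKVRMHYNIHWHHGKMHSSAKGTMPVQILPRNQDNHADSMCRTVSKGCPVEYCQHF
YGNDNHTFVWHWSHVKRECFRLKNVPSTTSGYEEVVVTTTHIIIHSPTPYSKLHWAIDFE
SHSDSKQWFEMIPMEMVTKARMAFVKPWNWMIVSRKEFEPFCITAAFFHRSLNLNDIGTH
RSPHTAFRWHLCRNPPRARIHIVYLYGVWCMGKFSDGLFYSNFWCGQYPYRCMNLSMATW
YTFSIWNVLRAIHDLTSQVLVYGHEWEDIMFESYNMPVPRKAHSAVEKDKQCFAASHQEF
GTTCQVVRNLFWRNRAMGVKRYPTVRYHLDIHQEISQITEGYFKYCELFISHYIETPWIC
HCSFAFVQIVYIWRSWCFSAPYFYYGVNGQAAEIQYKKLMNDYDLWSHAECSERNVKDYM
LNCWCWPRHLQGKMPNNCCNEPHETVMMWSGSMTRDDLMYCCYLTAIIPVFMFNDSIEHD
CPNGHQTDNPTMQTKKFSHVLAVAVQKSDCWWRNKTKVMMFDHSWNVVHWCFCHMSLCMP
DEVCECGGWHPTDFCGFEHDTKKFHVHTKACCEHSDIYAFMRPVRPFAWAGHCGGCGNMH
NFISDKWWIFVGCIPMEPVMQIEYSLPKSKFSGHWGCPAPFVMCEGPHCVALMLDVNLNM
KWYYAEIGTKPESFSLEMRDERQKWWNWDFRNNYCFKQNRTDWTENMAGFLMFPFLILCG
RQTGDEWGWYYYYQEDYCQQVPSPT
>NRDJ_SYN Class II (NrdJ) representative (synthetic)
GEINIKVRMHYNIEWHIGKTHSDKKGTRWVQVLPRNQDNHTARVCRTVSKGCPVNYQQHF
YPDDNHMFGNHWSHTKRECSRLKEVPSTTSGYIEVVGTGTHIICWSPTPYSKQHWATCFE
SHHDSKQWFEYIPMEMVTKARNATVKPWNKMIVRRKQFEPFCIDIAFFHRSLNLNDIGFH
RSPHTAFRWHLCWNPRYARIHIVYLYMNWCMVKFSCGWFGSNFWCGQYAYRRDNLCMAND
PTFSSWNVLRAIGSLTEIVLVYGNLWEDLMFESTNILVKRKAHSAVEKDTQCFMAHPQEQ
GTTCQVVRQLFWRNRAMGRKYNPSNRYHLDVHNEISQITEGYCKYCEQPIRQSIETPPIC
HCSSSHVQIYYIWFSSCFSAPYFYRTWCGYAAEAGQDYLMRNYRLWSHAEPSERNVKWYM
LNCWAWYRHLQEKMPNNCCNEPHEYPMMSSSSMNRTDLMYCCYLTAGLPVNMFNDSWEHD
CPNEHQTDNWNMQIKWESHVLAVAFHKSDCWWRQRTKVMMFDHSWFVVHWCCCVMSLCMP
DEVFECGQWHPTIFCPFEHDTSVAHVVWKACCEHSIIAAFMGNVRHFAWVGHNGNCCNMH
NFISDPWWIFVGCKPMHNVMQIEYSLPKSKFSTHWGCPAPLAMWEGPHCVALTLGVNLNM
KWYYAELGTKPEMFSLWNRDERQMWWNWDFRGNICTKANRTDLTENMAGFLMFPFLIQPG
RQTGDDWGWGAYYQEDYCCTVWSHN
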