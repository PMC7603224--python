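>LC3A_partner1 synthetic interactor demo group=LC3A
DTCCQTNSFAIPVYNQFNWGEVNQCNQMRDNSTVRTSEWYKHWRYIQTGRWDDMLMTNGQ
MKHIACACLCGPVRSACPFITLCDMVWFDHAFPFWGEAQSWGEFMPFWHLESKHVHITSP
GIIHGSQRFFTPEHRYSEQFGSPWKQHRFHVCNSPVTITPSTWLNHCTNLVQYDFPIAHK
QVVWMKWCISKQFWALYGRQHGNHAAMIL
>LC3A_partner2 synthetic interactor demo group=LC3A
TENGDVIQSFRIVHLCLVFECECMSYLGGHDKCHCEFTSQHRQFNGAEGMISHTVAPDTT
YIYYASYVDDYYIYCYFSAAVIWEYYFVYMWIFEWFQQLDHAYDVTDFRGVMCKMWSKFW
SPQVWWYWLSMFWVKVQFRCDLDIHESQLMYS
>LC3A_partner3 synthetic interactor demo group=LC3A
PIVHLDFQHKIFTKMLSIKRVIKWLGRVPDKCMYVIHAVCWLYECEMQHVSWWQAWPLLR
ICWGIDIWYEECVKSSKPDTAVIMDDPTYEATLSFLHCVIRTSEMFHGPQGNKIACSKFD
QQAQNAGMQRKGRFGYERSVWPETVQLWPMLPKHTCEQQSMYEKTVYRAGEHRLVFLSGK
HENWLTGYKELL
>LC3A_partner4 synthetic interactor demo group=LC3A
VSNGRANLCSMKSMFFYDCMWFFVPCHAQRGLTTDEIFIADIRCMCRDYKKTCKLFEWQM
IEKQYFTGMKHYGVKQNTFLSVKSSYMAPRRYPHAFGMPNAFFWVVMATCDREWPLVSPH
PWEDRKSAYIVTQLQEWGTMVKTQGHMARNPNYGPYEEQACVCHLAVPWWQKSFDYKWPV
LNY
>LC3B_partner1 synthetic interactor demo group=LC3B
WQCPRLYSTVRDKKKGLDPDTFQWCFLYWMEVWQFMQRRVFECGRWTLRKSWFHPIRVLY
IRMWVLFLDSGPPCNNYNAHCFPINNAGFSFQVMKRIKVMLCPNAIVFGPKLVGCRYKAK
DMYKNLQNITKNYAYAQLRNTIGIYHCYMAQQRRTSPAFDHYWNKIEGTRFDEHHYPYPV
LQRACRWISSQWETPESTLNHDQSIVPDNKNHDEPKFY
>LC3B_partner2 synthetic interactor demo group=LC3B
SCQSCACYIMGWWWHRAVQEFIFYQPICTHGAYLNFHIQHKSSNVEAQWIEYMLYEQLWK
EQDKFFRLEVRMHFGKMVLQYPIVPMVWELVKVLTEPFHDNWQSMAHTPIGWSECEWLPW
TSNHGRSTGPCDNTIRYIDHNDQYTCWQAWIPQVDKQCP
>LC3B_partner3 synthetic interactor demo group=LC3B
IGIGRLQDRHSGGFKWYKFYRSNCKPDFKYFKQWEELDAWMKQVKWCASQETFFKNGTEQ
EFGIWNVIRGEYTYAVIERRSPDYHPIAMRREEHFTDMKPVNCYQIFHAENQCLYYNGHG
RAPYMRQM
>LC3B_partner4 synthetic interactor demo group=LC3B
KTLDDNNWTAWHKSNYTVGNRGGMPHCNMNNCYLMIKHKVQCEKQPQKTSWIHFYVPIFS
LQGFIEHCGCWNWINIQSNMYHNEIPFNTRMRLPNWFMKDGNDYKIEWWAPRKADGCDSY
DMQECFHCLWHWLDRFIFGTKHDKSMQAHKNGNLNCAHTDTGQTIIHTIALDNEHEHEQV
GSQY
>LC3C_partner1 synthetic interactor demo group=LC3C
CHCTDMGNIDHKHKCEFSRAHIKVHEFSEYCTIGDYAKLLEEPWPFPCDGGKFWRDGDHL
QHLVWNPSDPCGLPRGNAWYMELCDTPWCVDAEIDFCEKQNQWTAKIRADECKIKYPPMD
DLDICNTRRVCFDEFAITCVVYTQVGVWRNNAEPHYSIQPSTPLDDGTGGWIMHEPESHT
RQQFKQVGVYEDKEDQVSRL
>LC3C_partner2 synthetic interactor demo group=LC3C
MFEEPGHMVPLLNQQLPTTCMNVTDHTLYRKGEWLFHDPQGCTYKDWHPNFCYWRVDTDI
SPQHYMDWQRQCTFPYVIYVCVEQTKNRIYWSCFPMQCCCIGCKFQEMEQNTPFLKPDPT
CTWITIFSLVKSDQPTRHVLLHGNSPWRAFDLPDRTYHWNEFDGMMHFLFAFYGYKFYWI
VEPGGRLYNAVSNSKNINYWQYIVANCSWY
>LC3C_partner3 synthetic interactor demo group=LC3C
LTENYMVQNKCRITGEVSWYMCRRMGPVTLYYQFHPLMWCTEYYVYIDCRQYYGSNSRCC
GFTDHTCTFVWTGRQMSWFFFWVMAYMRNDGMNCHCTAVTEGGNCPVPSYQKEYQQSHVQ
CAMVCA
>LC3C_partner4 synthetic interactor demo group=LC3C
LEYWYYHFIRVFLKKWDKYPEWINDKLQEEAHEKAAWSARVQGDNLDRRGMLHMTGRWHS
APYQICKFVGSLYGACPLVLPCTDSWMKAYWFWFRAAVMHDTARHCFGELFRTAHWPIHC
LRRAHDENKSFGCTAAWGSEYRNVIAWNGECLHFPLYLTVACTYCCFQPLNYKHIDACFT
RLVH
>GABARAP_partner1 synthetic interactor demo group=GABARAP
ETPFKALQMHYMEQHPMFSAPGVLVDEEKQHEIMFFQVQRYCWMRAVYMALFADVQVMAS
IWIKSHNVMEGRAKSMPWPDPRVVYHDQFGYCPFQPHFVHWIYSTKKGQRWDKYLSKINN
RHYGCLRTLHCKTWARKQWVLHPCNWGILNCWIYLKLGTIWIIHLPHADGVFRQRQKF
>GABARAP_partner2 synthetic interactor demo group=GABARAP
THKETQMATFPIFKVACCEGIEDLMWKCASAPMAFFIKDLVHWLWRPVSWDQKYCVYTAF
LQADKFIQKAGQTRFPRVAKDLIYMISGYNSGKGISPWWEQKTSFGVWSMVKVFYMQCGE
NLKRKNTQMQCKHKNYRKYHIHVLT
>GABARAP_partner3 synthetic interactor demo group=GABARAP
VGSLQHWLEGLTMVPIHVGGVKEPANNPSLYCMQANWAAVDYPLEFIWMPPMQHNVLTRT
FYAHQQLEINLDTHGGNVVIDQFSSFINVGQPDFCHNAQMVKFGEFHQPPGWMYKRTEEW
HILEWAMGDQTYEVMDHEFYINKRNFLTVVHDKQTLGINTTLFAYWRCVFYPHWFQQRY
>GABARAP_partner4 synthetic interactor demo group=GABARAP
PEMWLLLYFHEYKVALTITFSESHSRLDLYSWEQDRAINICQNKKGPHTKREQIVWWNKM
PHRWMLECSREVMAWLWYNLNPEDHHELNRPHPQHPGDLSMRQFSSVPGSVWDNKGFVYV
GEVYMPVPEGQQFLTKGLQKSFRLKFVWLYICHACFSRPVWTMGEMAALMWKTARAQHYD
GTVVDFKGEPEMWYCRFYSDVRC
>GABARAPL1_partner1 synthetic interactor demo group=GABARAPL1
RQTFINQTMMIMLKSIQMWHIMGFFDFYQLVRDLPFPSHGRMHFYYHPWLGMRSIDQVYI
DSWIRWNLDCALHTYGHYGNGYWRWEDEQDVRHYHLVAGWIFLDADASWMQDMDKKNCFV
FWYVIETFYVHFEWEYIIDSWREVCENSLQVKCSWHCDNSMWNEDATVSSWFAERG
>GABARAPL1_partner2 synthetic interactor demo group=GABARAPL1
PHDALTGGFAMLNLMHRRGAFGPLCRHWYCFMACFYNIHQLSQFTRNYLDVCLGQPNWAT
FSFFFWMSLVYQEVFVTEMMHRVHSCCMDGTGVKLECNMQEHFFTQGDMHMNPKRVTCSC
YYEKWPKYQENYLIYPLILTTPAHRATAVFETENFQMKHGNTSKEILIYFRCFEVIDNRA
WMSTPKIEKRTAMFGAGPPRIKMSPPYLHTICA
>GABARAPL1_partner3 synthetic interactor demo group=GABARAPL1
RKESRFLDVFDTWFQNIGFTFEYECRMCFLWVDHLVPCMVQYTHIPVGYSNWMQLRFPGI
FYCEREQSLMNTFRRARLNTNFMNYVTFMLIMSSFATKEACTWIIIRQQFYLAPKDSLHC
HQGGGWPKECYSGTTEWGWGQNKMQNRAKRFGDNFAGAMQMMPYDNPSDDHRQQERKHRS
QFIQKDIMAQSCVVRRDHHSKDTSERRTSVVN
>GABARAPL1_partner4 synthetic interactor demo group=GABARAPL1
KIYWWHYKKGCMHEKQWKYFQFKECPQRATKTTHPEYVYVTDWGGENCACAACKEKGMWL
TYSQPMCAEGVRYYIFQDTRQDGIINNVVLHHHGHQFERCVSGWDLFLEPFSYTDPRYYC
DPGPVWWTNQGVAQSRRDIMIQDTIDYYMNQHMGIHFGNAKYDMAPAKPPYDFQQNSYLY
LSVEMHRMKEQYVKVLFVKSMITKLWIQP
>GABARAPL2_partner1 synthetic interactor demo group=GABARAPL2
VESHPQGTCHKVDTNHQYIPCKWFDWLGSVDCAWKPTLITYWYMNLCGYNRVGVEGFVTL
QYGCLVHWHKRKAFYVVLYNFAPMHHWAVVGQMDTRKEYSIWIHDPQAWMRVEWNNRSEA
SDLFWVGLRKMYLVSDGLCSPPRRCNKFKRSYMPHMNKYNREYAVEQHKITCIGTPAGRT
WNIREYESNQPFPGLTNSIEDAIANCNE
>GABARAPL2_partner2 synthetic interactor demo group=GABARAPL2
DLPYMPSAMEYAYTLHTIFWVTKSRWPQNDGSLAQTPVASHRGRSTTTHYRFREYRKLSG
GQCCKKFAQEPTKNCEPWVYGTTMKRVPNTVLSKDTKHTKHLFKCECHNTTISTYWHHIC
FPSWIIQQYDGMCTLRHKDCYFTLVIISCVSSCMWPP
>GABARAPL2_partner3 synthetic interactor demo group=GABARAPL2
SDWTNWYGFHKELSHVPRISGEWEWLEFIQLKKDPSARILHMWPMYGWHLSKDTVFIRGV
VHPWAPEFCPWLNNEYDHSCVYAYIQIVRNNHQYHKEQMTHYMSFPAKRGPNKSLGHDQC
GDYSIMGSLVPQGHAHRGKTYGRRWNIGWPKNVRLNSSSPWFMIELKGSLELWH
>GABARAPL2_partner4 synthetic interactor demo group=GABARAPL2
WLCIFMECMPNQEMQHEQTDKITCTCTYWVLCYNLVKFDLRFYTEDELVNRVCPGYSFYY
KVWQATPYNHATIHVCSCCQRFFDLWTSVFRATVSIGRLCSGLIGNQMNFLVWCRITCLI
SSCSDSWARIFQREFIVRECMMNTPSQVYMKERQKNHEPGNLAARLRRQQWNGNICGILH
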