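>LC3A synthetic reconstruction of human MAP1LC3A; not a database record
MPSDRPFKQRRSFADRCKEVQQIREQHPSKIPVIIERYKGEKQLPVLDKTKFLVPDHVNM
SELVKIIRRRLQLNPTQAFFLLVNQHSMVSVSTPIADIYEQEKDEDGFLYMVYASQETFG
V
>LC3B synthetic reconstruction of human MAP1LC3B; not a database record
MPSEKTFKQRRTFEQRVEDVRLIREQHPTKIPVIIERYKGEKQLPVLDKTKFLVPDHVNM
SELIKIIRRRLQLNANQAFFLLVNGHSMVSVSTPISEVYESEKDEDGFLYMVYASQETFG
MKLSV
>LC3C synthetic reconstruction of human MAP1LC3C; not a database record
MPPPQKIPSVRPFKQRKSLAIRQEEVAGIRAKFPNKIPVVVERYPRETFLPPLDKTKFLV
PQELTMTQFLSIIRSRMVLRATEAFYLLVNNKSLVSMSATMAEIYRDYKDEDGFVYMTYA
SQETFGCLESAAPRDGSSLEDRPCNPL
>GABARAP synthetic reconstruction of human GABARAP; not a database record
MKFVYKEEHPFEKRRSEGEKIRKKYPDRVPVIVEKAPKARIGDLDKKKYLVPSDLTVGQF
YFLIRKRIHLRAEDALFFFVNNVIPPTSATMGQLYQEHHEEDFFLYIAYSDESVYGL
>GABARAPL1 synthetic reconstruction of human GABARAPL1; not a database record
MKFQYKEDHPFEYRKKEGEKIRKKYPDRVPVIVEKAPKARVPDLDKRKYLVPSDLTVGQF
YFLIRKRIHLRPEDALFFFVNNTIPPTSATMGQLYEDNHEEDYFLYVAYSDESVYGK
>GABARAPL2 synthetic reconstruction of human GABARAPL2 (GATE-16); not a database record
MKWMFKEDHSLEHRCVESAKIRAKYPDRVPVIVEKVSGSQIVDIDKRKYLVPSDITVAQF
MWIIRKRIQLPSEKAIFLFVDKTVPQSSLTMGQLYEKEKDEDGFLYVAYSGENTFGF
>ATG8_YEAST synthetic reconstruction of S. cerevisiae Atg8; not a database record
MKSTFKSEYPFEKRKAESERIADRFKNRIPVICEKAEKSDIPEIDKRKYLVPADLTVGQF
VYVIRKRIMLPPEKAIFIFVNDTLPPTAALMSAIYQEHKDKDGFLYVTYSGENTFGR
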