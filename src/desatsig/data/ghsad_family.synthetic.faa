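>GhA-SAD1 synthetic scaffold sequence
AVLSETMGSEIQDGAGFVSKAKDIELAFVPLTNRENLFSMLEEIRFAARLGASRIRIGVT
LTATYFKSFDFAGWDNMTAWGAITVYSYYRIGKRLGDAFLSTDMTSEYINRSVPQPVSQN
NDPVQLTKGLAKAKKEMIRTLNLIEVFSMAGPKCYFYYSQWESKKADAALVGAGGESIIG
SAFPSTEVQDPQCTRSIDISFPATQILELLGFDSDTNYAGSAPIRNGVFTPFILVGPIPV
GVALGTAPKEVIRTLPRLEACSQKVVNLTSVNDSIKLEPVNTGDNEKQANKQLWNVSIEL
GEDHPSRWKGHTNKAMIVRPGTPATLDNKTLQMAGQEMAHIPEPLQTGRDENRSLSHAGA
NQYTSIANDMNAVQAFHATGDKLQCSYWAFVALKGDLLIAYSAIERVHTDSVGNQFNAT
>GhA-SAD2 synthetic scaffold sequence
NFNLMGGKSQYEKPHPSPVGGANVEMKLKMGLIELAFVPLVNREGLFSMLEEIRFAARLG
ASRIRIGVTLTATYFKSFDFAGWDNMTAWGAITVYSYYRIGKRLGDFFLSTDMTSEYINR
SVPQPVSQNNDPVQLTKGLAKAKKEMLRTLNLIEVFSMAGPKCYFYYSQLESKKADAALV
GAGGESIIMSAFPSTEVQDPQCTRSIDIYFPATQILELLGFDSFTNVAGSAPIRNGVFTP
FILVGPIPVGIALCTAPKEVIRTLPRLEACSQKGVNLTSVVDSIKLEPENTCDNEKQANK
QLWNVSIELGEDHPSRWKGHTNKAMIVRPGTPATLDNKTLQKAGQEMVHIPEPLQTLRDE
NRSLSHAGANQYTSIAQDMNAVQAFHATGDKLQCSYWAFVALKGDLLIAYSAIERVMTDS
VGNQFNAT
>GhA-SAD3 synthetic scaffold sequence
SKNDTHLWAKSVLLQPGPVVERIELAFVPLVNREGLFSMLEEIRFAARLGASRIRIGVTL
TATYFKSFDFAGWDNMTAWGAITVYSYYRIGKRLGDFFLSTDMTSEYINRSVPQPVSQNN
DPVQLTKGLAKAKKEMIRTLNLIPVFSMAGPKCYFYYSQLESKKADAALVGAGGESIIGS
AFPSTEVQDPACTRFIDIYFPATQILELLGFDSFTNVAGSAPIRNGVFTPFILVGPIPVG
IALGTAPKEVIRTLPRLEACSQKVVNLTSVVDSIKLEPENTGDNEKQANKQLWNVSIELG
EDHPSRAKGHTNKAMIVRPGTPATLDNKTLQKSGQEMVHIPEPLQTLRDENRSLSHAGAN
QYTSIAQDMNAVQAFHATGDKLQCSYWAFVALKGDLLIAYSAIEEVMTDSVGNQFNAT
>GhA-SAD4 synthetic scaffold sequence
RAHICEEQLGEHEVSKDMLDVSIAGIYLGSQKPIELAFVPLVNREGLFSLLEEIRFTARL
GASRIRIGVTLTATYFKSFDFAGPDNMTAWGAIEVYSYYRIGKRLGDFFLSTDMTSEYIN
RSVPQAVSQNNDPVQLTKGLCKAKKEMLRTLNLIEVFSMAGPKCYFYYSQLESKKADAAL
VGAGGESIITSAFPSTEVQDPQCTRSIDIYFPATQILELLGFDSFTNVAGSAPIRNGVFT
PFILVGPIPVGIALGTAPKEVIRTLPRLEACSQKVVNLTSVVDSIKLEPENTGDNEKQAN
KQLWNVSIELGEDHPSRWKGHTNKAMIVRPGTPATLDNKTLQKFGQEMVHIPEPLQTLRD
ENRSLSHAGANQYTSIAQDMNAVQAFHPTGDKLQCSYWAFVALKGDLLIAYSAIERVMTD
SVGNQFNAT
>GhA-SAD8 synthetic scaffold sequence
LMESKTQGSTNLGDILMKMSAQVARADGTLLEIELAFVPLVNREGLFSMLEEIRFAARLG
ASRIRIGVTLTATYFKSFDFAGWDNMTAWGAITVYSYYRIGKRLGDFFLETDMTSECINR
TVPQPVSQNNDPVQLTKGLAKAKKEMLRTLNLIEVFSMAGPKCYFYYSQLESKKADAALV
GAGGESIIGSAFPSTEVQDPQCTRSIDIYFPATQILELLGFDSFTNVAGSAPIRNGVFTP
FILVGPIPVGIALGTAPKEVIRTHPRLEACSQKVVNLTSVVDSIKLEPENTGDVEKQANK
QLWNVSIELGEDHPSRWKGHTNKAMIVRPGTPATLDNKTWQKAGQEMVHIPEPLQQLGDE
NRSLSHAGANQYTSIAQDMNAVQAFHATGDKLQCSYWAFIALKGDLLIAYSAIERVMTDS
VGNQFNAT
>GhA-SAD9 synthetic scaffold sequence
GKQLNVKHAKLDNAVGIMQGRLVLKRLELSKQIELRFVPLVNREGLFSMLEEIRFAARLG
ASRIRIGVTLTATYFKSFDFAGWDNMTAWGAITVYSYYRIGKRLGDFFGSTDMTSEYINR
SVPQPVSQNNDPVQLTKGLAKAKKEMLRTLNLIEVFSMAGPKCYFYYSQLESKKADAALV
GAGGESIIGSAFPSTEVQDPQCTRSIDIYFPATQILELLGFDSFTNVAGHAPIRNGVFTP
FILVGPIPWGIALGTAPKEVIRTLPRLEACSQKVVNLTSVVDSIKLEPENTGDNEKQANK
QLWNVSIELGEDHPSRWKGHTNKAMIVRPGTPATCDNKTLQKAGQEMVHIPEPLQTLRDE
NRSLSHAGANQYTSIAQDMNAVQAFHATGDKLQCSYWAFVALKGDLLIAYSAIERVMTDS
VGNQFNAT
>GhD-SAD1 synthetic scaffold sequence
HDEAGLYAFYVATKANDWLDLMIRMEAIKVAKIELAFVPLVNREGLFSMLEEIRFAARLG
ASRIRIGVTLTSTYFKSFDFAGWDNMTAWGAIRVYSYYRIGKRLGDFFLSTDMTSEYINR
SVPQPVSQNNDPVQLTKGLAKAKKEMLRTLNLIEVFSMAGPSCYFYYSQLESKKADAALV
GAGGESIIGSAFPSTEVQDPQCTRSIDIYFPATQILELLGFDSFTNVAGSAPIRNGVFTP
FQLVGPIPVGIALGTAPKEVIRTLPRLEACSQKVVNLTSVVDSIKLEPDNTGDNEIQANK
QLWNVSIELGEDHPSRWKGHTNKAMIVRPGTPATLDNKTLQKAGQEMVHIPEPLQTLRDE
NRSLSHAGANQYTSIAQDMNAVQAFHATGDKLQCSYWAFVALKGDLLIAYSAIERVMTDS
VGNQFNAT
>GhD-SAD2 synthetic scaffold sequence
SNIHFGKELGGMLLTVVSQNIHEIELCFVPLVNREGLFSMLEEIRFAARLGASRIRISVT
LTATYFKSFDFAGWDNMTAWGAITVYSYYRIGKRLGDFFLSTDMTSEYINRSVPQPVSQN
NDPVQLTKGLAKAKKEMIRTLNLIEVFSMAGPKCYFYYSQLESKKADEALVGAGGESIIG
SAFPSTEVQDPQCTRSIDIYFPATQILELQGFDSFTNVAGSAPIRNGVFTPFILVGPIPV
GIALGTAPKEVIRTLPRLEACSQKVVNLTSVVDSIKLEPENTGDNEKQANKQLWNVSIEL
GEDHPSRWKGHTNKESIVRPGTPATLDNKTLQKAGQEMVHIPQPLQTLRDENRFLSHAGA
NQYTSIAQDMNAVQAFHATGDKLQCIFWAFVALKGDLLIAYSAIERVMTDSVGNQFNAT
>GhD-SAD3 synthetic scaffold sequence
GQTTNDSSEYKDEAEILFGPRLTLLKYRGAEGTIELAFVPLVNREGLFSMLEEIRFAARL
GASLIRIGVTLTATYFKSFDFAGWDNMTAWGAITVYSYYRIGKRLGDFFLSTDMTSEYIN
RSVPQPVSQNNDPVQLTKGLAKAKKEMLRTLNLIEVFSMAGPKCYFYYSQLESKKADAAL
VGAGGESIIGSAFPSTEVQDPQCTRSIDIYFPATQILELLGFDSFTNVAGSAPIRNGVFT
PFILVGPIPVGIALGQAPKEVIRTLPRLEAISQKVVNLTSVVDSIKLEPENTGDNEKQAN
KQLWNVSIELGEDHPSRWKGHTNKAMIVRPGTPATLDNKTLQKAGQEMVHIPEPLQTLRD
ENRSLSHAGANQYTSIAQDMNAVQAFHATGDKLQCSYWAFVALKGDLLIAYSAIERVMTD
SVGNQFWAT
>GhD-SAD6 synthetic scaffold sequence
EPETIREVQQRLQRVAGYLEAQSLEDPAMTIKIELAFVPLVNREGLFSMLEEIRFAARLG
ASRIRIGVTLTATYFKSFDFAGWDNMTAWGAITVYSYYRIGKRLGDFFLSTDMTSEYINR
SVPQPVSQNNDPVQLTKGLAKAKKEMLRTLNLIEVFSMAGPKCYFYYSQLESKKADAALV
GAGGESIIGSAFPSTEVQDPQCTRSIDIYFPATQILELLGFDSFTNVAGSAPIRPGVFTP
FILVGPIPVGIALGTAPKEVIRTLPRLEACSQKVVNLTSVVDSIVLEPENTGDNEKQANK
QLWNVSIELGEDHPSRWKGHTNKAMKVRPGTPATLDNKTLQKAGQEMVHIPEPLQTLRRE
NRSLSHAGANQYASIAQDMNAVQAFGATGDKCQCSYWAFVALKGDLLIAYSAIERVMTDS
VGNQFNAT
>GhD-SAD4 synthetic scaffold sequence
ALVLCIDGGRAYTNSSKGALAEGANSSQGDQQDIELAFVPLVNREGLFSMLEEIRFAAAL
GASRIRIGVTLTAHYFKSFDFAGWDNMTAWGAITVYSYYRIGKRLGDFFLSTDMTSEYIN
RSVPQPDSQNNDPVQLTKGSAKAKKEILRTLNLIEVFSMAGPKCYFYYSQLESKKADAAL
VGAGGESIIGSAFPSTEVQDPQCTRSIDIYFPATQILELLGFDSFTNVAGSAPIRNGVYT
PFILVGPIPVGIALGTAPKEVIRTLPRLEACSQKVVNLTSVVDSIKLEPECTGDNEKQKN
KQLWNVSIELGEDHPSRWKGHTNKAMIVRPGTPATLDNKTLCKAGQEMVHIPEPLQTLRD
ENRSLSHAGADQYTSIAQDMNAVQAFIATGDKLQCSYWAFVALKGDLLIAYSAIERVMTD
SVGNQFNAT
>GhA-SAD5 synthetic scaffold sequence
RSVPQPVSQNNDPVQLTKGLAKAKKEILRRLNLIEVFSMAGPKCYFYYSQLESKKADAAL
VGAGGESIIGSAFPSTEVQDPQCTRSIDIYFVAIQILELLTFDSFTNVAGSAPINNGVFT
PFILVGPIPVGIALGTAPKEVIRTLPRLEACSQKVVNLTSVVDSIKLEPENTGDNEKQAN
KQLWNVSIELGEDHPSRWKGWTNKAMIVRPGTPATLDNKTLQKAGQEMVHIPEPLQTLRD
ENRSLSHAGANQYTSIAQDMNAVQAFHATGDKLQCSYWAFVALKGDLLIAYSAIERVMTD
SVGNQFNAT
>GhD-SAD5 synthetic scaffold sequence
ITVVRGGSIMVTDRALLESPLVYARYANILFGIELAFVPLVNREGLFSMLEEIRFAARLG
ASRIRIGVTLTATYFKSFDFAGWDNMTAWGAITVYSYYRIGKRLGDFFLSTVMTSEYINR
SVPQPVSQNNDPVQLTKGLAKAKKEMLRRLNLIEVFSMAGPKCYFYYSQLESKKADAALV
GAGGESIIGSAFPSTEVQDPQCTRSFDIYFVAIQILELLTFDSFTNVAGSAPIRNGVFTP
FILVGPIPVGIALGTAPKEVIRTLPRLEACSQKVVNLTSVVDSIKLKPENTGDNEKQANK
QLWNVSIELGEDHPSRWKGHTNKAMIVRPGTPATLDNKTLQKAGQEMVHIPEPLQTLRDE
NRSLSHAGANQHTCIAQDMNAVQAFHATGDKLQCSYWAFVALKGDLLFAYSAIERKMTDS
VGNQFNAT
>GhA-SAD6 synthetic scaffold sequence
GDILEKVTGAKYVKEIHLGMEAEEKKRDKVLPLFTELAFVPLVNREQLFSMLEEIRFAAR
LGASRIRIGVLLTATYFKSFDFAGWDNMTAWGAITVYSAYRIGKRLGDFFLSTDMTSEPI
NRSVPQPVSQNNDPVQLTKGLAKAKKEMLRTLNLIEVFSMAGPKCYFYYSQLESKKADAA
LVGAGGESIIGSAFPSTGVQDPQCTRSIDIYFPAAIILELLTFDSFTNVAGSAPIRNGVF
TPFILVGPICVGIALGTKPKEVIRTLPRLEACSQKVVNLTSVVDSHKLEPENTGDNEKQA
NKQLWNVSIELGEDHPSRWKGHTNKAMIVRPGTPATLDNKTLQKAGQEMVHIPEPLQTLR
DENRSLSHAGANQYTSIAQDMNAVQAFHATGDKLQCSYWAFVALKGDLLIAYSAIERVMT
DSVGNQFNAT
>GhA-SAD7 synthetic scaffold sequence
ETDCEAGANLVWPKIPGLRVGGDRHIKVSSIELAFVPLVNREGLFSMLEEIRFAARLGAS
RIRIGVTLTATYFKSFDFANWDNMTAWGAITVYSYYRIGSRLGDFQLSTDMTSEYINRSV
PQPVSQNNDPVQLTKGLAKAKKELLRTMNLIEVFSMAGPKCYFYYDQHESKKADAALVGA
GGESIIGSAFPSTEVQDPQCTRSIDIYFSASQILELLGADSFTNVAGSAPIRNGVFTPFI
LVGPIPVGKALGTAPKEWIRTLPRLEACSQKVVNLTSVVDSIKGEPENTGDNEKQANKQL
WNVSIELGEDHPSRWKGHTNKAMIVRPGTPATLDNKTLQKAGQEMVHIPEPLQTLRDENR
SLSHAGANQYTSIAQDMNAVQAFHATGDKLQCSYWAFVALKGDLLIAYSAIERVMTDSVG
NQFNAT
>GhD-SAD7 synthetic scaffold sequence
VAAKDDFSNNCGSACEDNPREFTASPLMEGIELAFVPLVNREGLFSMLEEIRFAARLGAS
RIRIGVTLTATYFKSFDFAGWDNMTAWGAITVYSYYRIGKRLGDFFLSTDMTSEYINRSV
PQPVSQNNDPVQLTKGLAKAKDELLRTMNLIEVFSPAGPKCYFYYSQLESKKADAALVGA
GGESIIGSAFPSTEVQDPQCTRSIDIYFSASQILELLGADSFTNVAGSAPIRNGYFTPFI
LVGPIPVGIALGTAPKEVIRTLPWLEACSKKVVNLTSVVDSIKLEPENTGDNEKFANKQL
WNVSIELGEDHPSRWKGHTNKAMIVRPGTPATLDNKTLQKAGQEMVHIPEPLQTLRDENR
SLSHAGANQYTSIAQDMNAVQAFHATGDHLQCSYWAFVALKGDLLIAYSAIERVMTDSVG
NQFNAT
>GhD-SAD8 synthetic scaffold sequence
NDVNILAIPIRIEGICAAARRAAGYGGLMGARTIELRFVPLVNREGLFSMLEEIRFAARL
GASRIRIGVTLTATYFKSFDFAGWDNMVAWGAITVYSYYRIGKRLGDFFLSTDMTSEYIN
RSVPQPVSQNNDEVQLTKGLAKAKKEMLRTLNLIEVSSMAGPKCPFYYSQLESKKADAAL
VGAGCESIIGSFFPSTEVQDPQCTRSIDIYFMAAQILELLAYDSFTNVAGSAPIRNGVFT
PFILVGPIPVGIALGTAPKEVPRTLPRLEACSQKVVNLTSVVDSIKLEPENTGDNEKQAN
KQLWNVSIELGEDHPSRWKGHTNKAMIVRPGTPATLDNKTLQKAGQEMVLIPEPLQTLRD
ENRSLWHAGANQYTSIAQDMNAVQAFHATGDKLQCSYWAFVALKGDLLIAYSAIERVMTD
SVGNQFNAT
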