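>RcSAD1 synthetic scaffold sequence
IELAFVPLVNREGLFSMLEEIRFAARLGASRIRIGVTLTATYFKSFDFAGWDNMTAWGAI
TVYSYYRIGKRLGDFFLSTDMTSEYINRSVPQPVSQNNDPVQLTKGLAKAKKEMLRTLNL
IEVFSMAGPKCYFYYSQLESKKADAALVGAGGESIIGSAFPSTEVQDPQCTRSIDIYFPA
TQILELLGFDSFTNVAGSAPIRNGVFTPFILVGPIPVGIALGTAPKEVIRTLPRLEACSQ
KVVNLTSVVDSIKLEPENTGDNEKQANKQLWNVSIELGEDHPSRWKGHTNKAMIVRPGTP
ATLDNKTLQKAGQEMVHIPEPLQTLRDENRSLSHAGANQYTSIAQDMNAVQAFHATGDKL
QCSYWAFVALKGDLLIAYSAIERVMTDSVGNQFNAT
>AtFAB2 synthetic scaffold sequence
TFKSSGNSDYATEVSINQCRKLPPVVLRLYPGNWEVLVIELAFVPLVNREGLFSMLEEIR
FAARLGASRIRIGVTLYATYFKSFDFAGWDNMTAWGAITVYSYYRIGKRLGDFFLSTDMT
SEYINRSVPQPVSQNNDPVQLTKGLAKAKKEMLRTLNLIEVFSMAGPKCYFYYSQLESKK
ADAALVGAGGESIIGSAFPSTEVQDPQCTRSIDIYFPATQILELLGFDSFTNVAGSAPIR
NGVFTPFILVGPIPVGIALGTAPKEVIRTLPRLEACSQKVVNLTSVVDSIKLEPENTGDN
EKQANKQLWNVSIELGEDHPSRWKGHTNKAMIVRPGTPATLDKKTLQKAGQEMVHIPEPL
QTLRDENRSLSHAGANQYTSIAQDMNAVQAFHATGDKLQCSYWAFVALKGDLLIAYSAIE
RVMTDSVGNQFNAT
>AtAAD3 synthetic scaffold sequence
MGACHKSKGLEHFEIRLPREIVHVTDKGAKLAELDIELAFVPLVNREGLFSMLEEIRFAA
RLGASRIRIGVTLTATYFKSFDFAGWDNMTAWGAITVYSYYRIGKRLGDFFLSTDMTSEY
INRSVPQPVSQNNDPVQLTKGLAKAKKETLRTLNLIEVFSMAGPKCYFYYSQLESKKADA
ALVGAGGESIIGSAFPSTEVQDPQCTRSIDIYFSAFQILELLGFDSFTNVAGSAPIRNGV
FTPFILVGPIPVGIALGTAPKEVIRTLPRLEACSQKVVNLTSVVDSIKLEPENTGDNEKQ
ANKQLWNVSIELGEDHPSRWKGHTNKAMIVRPGTPATLDNKTSQKAGQEMVHIPEPLQTL
RDENESLSHAGANQYTSIAQDMNAVQAFHATGDKLQCSYWAFVALKGDLLIAYSAIEQVM
TDSVGNQFNAT
>AtAAD2 synthetic scaffold sequence
LEIKTELKNRRFRISGRIQIAGSDALNMNDLEDYTEKAHMASFNVIELAFVPLVNREGLF
PTLEEIRFAARLGASRIRIGVTLTATYFKSFDFAGWDNMTAWGAITVYSYYRIGKRLGDF
FLSTDMTSEYINRSVPQPVSQNNDPVQLTKGLAKAKKETLRTLNLIEVFSMAGPKCYFYY
SQLESKKADAALVGAGGESIIGSAFPSFENQDPQCTRSIDNYFSAFQILELLGFDSFTNV
AGSAPIRNGVFTPFILVGPIPVGIALGTAPKEVIRTLPRLEACSQKVVNLTSVVDSIKLE
PENTGDNEKQANKQLWNVSIELGEDHPSRWKGHTNKAMIVRPGTPATLDNKTLQKAGQEM
VHIPEPLQTLRDENRSLSHAGANQYTSIAQDMNAVQAFHATGDKLQCSYWAFVALKGDLL
IAYSAIERVMTDSVGNQFNAT
>Muc-PAD synthetic scaffold sequence
LFPESSNLPVFEPDGHELDNSVPASEALIICKSDIELAFVMLVNREGLFSMLEEIRFAAR
LGASRIRIGVTLTATYFKSMDFAGWDNMTAWGAITVYSYYRIGKRLGDFFLSTDMTSEYI
NRSVPQPVSQNNDPVQLTKGLAKAKKEMLRTWNLIEVFSMAGPKCYFYYSQLESKKADAA
LVGAGGTSIIGSAFPSTEVQDPQCTRSIDIYFPATQILELLGFDSFTGVAGSAPIRNGVF
TPFILVGPIPVGITLGTAPKEVIRTLPRLEACSQKVVNLTGVVDSIKLEPENTGDNEKQA
NKQLWNVSIELGEDHPSPWKGHTNKAMIVRPGTPATLDNKTLQLAGQEMVHIPEPLQTLR
DENRSLSHAGANQYTSIAQDMNAVQAFHATGDKLQCSYWAFVALKGDLLIAYSAIERVMT
DSVGNQFNAY
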