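v_gene,j_gene,cdr3_aa,source
TRBV17,TRBJ1-5,CNTRPWKPYKF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV26,TRBJ2-1,CTMYCIQGEKKMNF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV1,TRBJ1-4,CFGTPPSSAWEKF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV14,TRBJ2-3,CFQVIGPNWEF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV14,TRBJ1-3,CLEWERMMLAEEQECF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV12,TRBJ1-3,CCFCKLCMQFHQFYTF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV16,TRBJ1-4,CYLMMARWNPTFF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV19,TRBJ2-6,CRINRKYVMSLAVF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV12,TRBJ1-4,CDCEHMEWMMKCWLF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV20,TRBJ1-5,CNNDDSANFMF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV17,TRBJ2-2,CSPYMICECFYSF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV20,TRBJ2-6,CWVLNWMFLYVHNVF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV31,TRBJ1-3,CSTKWPWCDPWGQCLF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV13,TRBJ2-1,CLNNMDLDWMQYLQF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV14,TRBJ2-1,CGLGRQVPFCNF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV13,TRBJ1-1,CTGGEGWAIKYKEF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV15,TRBJ2-1,CGLRNVTWTWPYAIDSMF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV29,TRBJ1-6,CSRTIGLRCTYDNF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV16,TRBJ1-2,CGFRDYAYTINKFNF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV4,TRBJ2-5,CNNLSWNLPVAWF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV17,TRBJ1-3,CKWQNMMHGQEEGQF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV29,TRBJ1-1,CYIMTMGFCKMKRHPF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV23,TRBJ1-3,CDHAWMQCYAPCAF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV20,TRBJ1-1,CVWYPMRPQFKPF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV26,TRBJ1-6,CDESEHFIFRWLF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV13,TRBJ1-2,CHSCIHLPTCYMIIF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV23,TRBJ2-4,CVRRYCASQSNWMAF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV3,TRBJ1-6,CQCIRRMYAIAKLF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV14,TRBJ1-1,CMEEEHVPHFRPDFQF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV12,TRBJ2-1,CAGMMTGSFLYTHYKF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV17,TRBJ1-3,CIDKCRDHWGTVF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV19,TRBJ1-1,CQNEGSNRLNYF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV29,TRBJ2-1,CAFPEHWGWARMF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV5,TRBJ2-5,CPMVYRRRYTNYF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV14,TRBJ2-5,CKLELKCTIRF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV4,TRBJ2-2,CKYRWAMNMNFQYHFIF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV1,TRBJ2-6,CCKAINEWFLMCF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV26,TRBJ1-1,CNHHWRWLDFLF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV23,TRBJ2-2,CMYDPGLDRPTVYKYQF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV17,TRBJ2-4,CVTHFDFSMTHPENF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV17,TRBJ1-6,CPREQSCDWPF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV15,TRBJ1-3,CGHDCPTFWGWRGDIRF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV13,TRBJ1-6,CTKENDSRFAF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV2,TRBJ2-5,CYPRPTQASVVF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV12,TRBJ2-6,CKNAQKQCNKECMF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV19,TRBJ1-6,CMRPSVHAGYYHGF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV5,TRBJ2-2,CHWNGEDEQAVGQF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV12,TRBJ2-1,CWASYTYGNMPRLGF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV13,TRBJ2-6,CKDDHHLMPIGWSCF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV29,TRBJ2-5,CMTPGSEKYDWCNQF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV20,TRBJ1-3,CQRETSDPGAVISLHQF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV17,TRBJ2-2,CHCDHMNQAFVVTINF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV15,TRBJ1-1,CICHNKNECKQFF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV4,TRBJ2-5,CTRKCNWLKGF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV29,TRBJ2-6,CVNYTDSGGEQEMNPF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV31,TRBJ1-6,CATAQICQIWRHF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV1,TRBJ2-2,CYLNWYWYLGFSAF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV16,TRBJ1-3,CTKQHWFTTLLGDTEPWF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV12,TRBJ1-3,CIFWVTRFCSKEHDNF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
TRBV20,TRBJ2-4,CVHGPDGMQVHKCKF,synthetic stand-in panel (simulator-generated; not a published antigen panel)
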