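subject_id,group,sex,age,nyha,mwt,gfr,stroke,phenotype,cornea_verticillata,mutation,therapy
P01,FD,F,57,1,14,55.2,yes,Classic,yes,p.(Arg301Pro),E.R.T.
P02,FD,F,71,1,14,76,yes,Classic,yes,p.(Arg301Pro),P.C.
P03,FD,M,38,2,15,71.5,yes,Classic,yes,p.(Met1Val),E.R.T.
P04,FD,F,30,1,14,110,no,Classic,no,p.(Lys240ArgfsX29),none
P05,FD,M,65,2,21,78,no,Late-onset,no,p.(Asn215Ser),E.R.T.
P06,FD,M,53,2,10,50,yes,Classic,yes,p.(Cys63Tyr),E.R.T.
P07,FD,F,69,2,13,77,no,Classic,no,p.(Leu243Ser),none
P08,FD,F,61,2,14,75,no,Classic,yes,p.(Ser364Leufs*9),E.R.T.
P09,FD,M,35,1,12,130,yes,Classic,yes,p.(Ser364Leufs*9),E.R.T.
P10,FD,F,30,1,8,170,yes,Classic,yes,p.(Ser364Leufs*9),E.R.T.
P11,FD,M,60,1,1,19,yes,Classic,yes,p.(Arg112Cys),E.R.T.
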