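protein_id,peptide,labeled_peptide,light_mz,heavy_mz,charge,product_ions,rt_min,spike_fmol
ETR1,ISPNSPVAR,ISPNSPVA[Heavy R],470.7642,475.7683,2,y7+;y6+;y5+;y3+;y7++,13.25,10
ETR1,EGNVSISAFVAK,EGNVSISAFVA[Heavy K],611.3273,615.3344,2,y8+;y7+;y6+,23.30,50
ETR2,YIPGEVVAVR,YIPGEVVAV[Heavy R],551.8164,556.8205,2,y8+;y7+;y6+;y5+;y4+;y8++,20.47,5
ETR3,YIPPEVVAVR,YIPPEVVAV[Heavy R],571.8320,576.8362,2,y8+;y7+;y6+;y5+;y4+;y8++;y7++;b2+,21.69,10
ETR3,VPLLHLSNFTNDWAELSTR,VPLLHLSNFTNDWAELST[Heavy R],738.3832,741.7193,3,y8+;y7+;y6+;y5+;y4+;y3+;b12++,34.25,100
ETR3,LIQTLLNVAGNAVK,LIQTLLNVAGNAV[Heavy K],727.4405,731.4476,2,y12+;y10+;y9+;y8+;y7+;y4+;y3+;b4+;b5+,30.31,400
ETR4,DSSFNSAYNLPIPR,DSSFNSAYNLPIP[Heavy R],790.8888,795.8929,2,y9+;y8+;y7+;y4+,29.25,15
ETR4,SDPDVIQVK,SDPDVIQV[Heavy K],500.7691,504.7762,2,y7+;y6+;y5+;y7++,16.15,15
ETR4,VLPESVSR,VLPESVS[Heavy R],443.7533,448.7574,2,y6+;y5+;y4+;y6++,14.61,10
ETR5,SLSINDPDVLEITK,SLSINDPDVLEIT[Heavy K],772.4143,776.4214,2,y9+;y8+;y7+,28.93,50
ETR6,FWLNQEVEIVR,FWLNQEVEIV[Heavy R],716.8828,721.8869,2,y8+;y7+,31,25
ETR6,GVEVLLADYDDSNR,GVEVLLADYDDSN[Heavy R],783.3757,788.3799,2,y9+;y8+;y7+,27.9,100
ETR7,SLPIDDPDVLEITK,SLPIDDPDVLEIT[Heavy K],777.9167,781.9238,2,y9+;y8+;y12++,30.51,15
ETR7,GLQVLLADDDDVNR,GLQVLLADDDDVN[Heavy R],771.8916,776.8957,2,y9+;y8+;y7+;b8+,25.98,100
CTR1,IPSIESLR,IPSIESL[Heavy R],457.7689,462.7731,2,y7+;y6+;y5+;y4+;y7++,21.5,15
CTR1,LNPPQVIAAVGFNR,LNPPQVIAAVGFN[Heavy R],748.4226,753.4268,2,y10+;y9+;y8+;y12++;y11++,29.76,15
CTR2,YAPNEVPR,YAPNEVP[Heavy R],473.2431,478.2472,2,y6+;y5+;y4+;y6++,14.35,10
CTR2,LVIPAYVDQLNSR,LVIPAYVDQLNS[Heavy R],744.4145,749.4186,2,y10+;y9+;y8+;y7+;y10++;b3+,28.38,10
CTR3,ASASAASAETLSHR,ASASAASAETLSH[Heavy R],679.8366,684.8407,2,y8+;y7+;y6+,12.78,5
EIN2,GVSENAQSFISDGPGSYK,GVSENAQSFISDGPGSY[Heavy K],921.9289,925.9360,2,y11+;y10+;y9+;y5+,23.66,50
EIN2,VESSAYIPSGSAR,VESSAYIPSGSA[Heavy R],662.3306,667.3347,2,y9+;y8+;y7+;y6+,16.31,5
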