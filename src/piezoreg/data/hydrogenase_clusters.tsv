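name	locus_range
Mrp-Mbh	A7C91_RS04230-04165
Fdh1-Mfh1-Mnh1	A7C91_RS06945-07020
Fdh2-Mfh2-Mnh2	A7C91_RS04320-04240
F420-reducing hydrogenase	A7C91_RS_04340-04330
SHI	A7C91_RS08740-08725
SHII	A7C91_RS06200-06185
Mrp-Mbs	A7C91_RS08510-08450
Nsr	A7C91_RS06865
SurR	A7C91_RS07565
Pdo	A7C91_RS07570
Nfn I	A7C91_RS06205-6210
Nfn II/Xfn	A7C91_RS02315-2310
Nfn III	A7C91_RS02425-2430
Fdh3	A7C91_RS08745-08770
RNR	A7C91_RS02975
ATP synthase	A7C91_RS03355-03315
TrxR	A7C91_RS04130
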