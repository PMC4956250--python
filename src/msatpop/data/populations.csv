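id,locality,country,n,latitude,longitude,status
P01,Petrinjski Kras Soligrad,SVN,23,45.57,13.91,indigenous
P02,Petrinje,SVN,24,45.57,13.90,indigenous
P03,Krk,HRV,25,45.23,14.57,indigenous
P04,Pag,HRV,25,44.43,15.04,indigenous
P05,Pirovac,HRV,24,43.83,15.72,indigenous
P06,Sparadici,HRV,24,43.63,15.96,indigenous
P07,Unesic,HRV,25,43.73,16.16,indigenous
P08,Vis,HRV,24,43.03,16.14,indigenous
P09,Peljesac,HRV,25,42.98,17.27,indigenous
P10,Konavle,HRV,25,42.60,18.25,indigenous
P11,Hutovo blato,BIH,24,43.04,17.71,indigenous
P12,Mostar,BIH,25,43.33,17.75,indigenous
P13,Medugorje,BIH,25,43.18,17.69,indigenous
P14,Trebinje,BIH,22,42.71,18.40,indigenous
P15,Pjesivci Niksic,MNE,24,42.36,19.23,indigenous
P16,Sutorman Bar,MNE,22,42.15,19.12,indigenous
P17,Llogora,ALB,24,40.20,19.59,indigenous
P18,Mt. Rrenci,ALB,23,41.83,19.58,indigenous
P19,Mt. Jablanica,MKD,24,41.32,20.58,indigenous
P20,Mt. Karaormar,MKD,22,41.39,20.62,indigenous
P21,Lygeri,GRC,24,40.33,21.71,indigenous
P22,Skiti,GRC,22,40.32,21.65,indigenous
P23,Vermice,KOS,23,42.17,20.58,naturalised
P24,Mirusha,KOS,24,42.52,20.57,naturalised
P25,Pancevo,SRB,20,44.85,20.72,cultivated
P26,Gradiste,SRB,24,43.33,22.17,indigenous
P27,Bacau Motoc,ROM,24,46.36,27.10,cultivated
P28,Bihor Avram Iancu,ROM,22,46.67,21.53,cultivated
P29,Chishinau,MDA,23,47.36,28.85,naturalised
P30,Lopatica Cahul,MDA,24,45.95,28.41,cultivated
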