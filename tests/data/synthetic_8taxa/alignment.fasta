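>t1
QAK-T--K-VNIWHLAMYSWKVPDEASAGEF--AY-RKGFQ-TKTE-DVG-AQ--RGH-I
LTPGIGREEE-LISSPEYFLSITKMSE-LSVGETRP-GSAGF-FLEG-DVPGK-G-AIVE
>t2
QAK-T--KSVNIWQLAMYSWKQPDSASSGEF-GAQHRKGFK-TKTELDVG-AQ--RGH-I
LTPGIGREEE-LISSPEYFLSIDKLATPLSLGESRP-GCSGFQFLEG-DVPGK-G-AIVE
>t3
QARFTQ-KSVDIWNLALYSWQPPERASCGEF-GAQHRKNFK-TKSELDVQQAQ--RNQ-I
LTPGI-RDEEETVSSPDYFLAIDRLAE-LNVGATRP-GYTGVTFLE--DVPGK-G-ALVE
>t4
NAE-TQ-KSVNIWKLAMYSWKQPDQASDGE--GAQHSKGFK-TKSELDVEQAQ--RGHMI
-VPGVGRDEAQ-VSAPKYF--LDRLSE-LSVGETRP-GCTGVRFLE--DVPG--G-DIVE
>t5
QA--TQ-ISVNIWHLAVFSWQQPDSASTGEF-GAQHRKGFK-TKSELDVQQAQ--RGH-L
LVPGIGRGEEDLVSSPKYFLAIDRLSE-LSVGEVRD-GC-GVKLLEG-DVPNK-G-L-VE
>t6
QAS-TQ-KSVNIWHLAMFSWSQPDSASSGEF-SAQH-KG-K-TKSELNVQQAQ---GH-I
LTPGIGRSEEELVSSPEFFLAID-LAE-LNVGETRS-GCSGVKLLEG-DVPNK-R-L-V-
>t7
QAT-TQ-KSVQIWHLALFSWQQPDSASTGE---AQHAKG-K-TKSELDVQQAQ--RGH-V
LTPGIARSDEELVSSPKYFLAIDKLSQ-LSVGA-QS-GCSGVKLLEG-DVPNK-R-L--E
>t8
QAS-TQ-KSVQIWHLALFSWQQPDSASTGD---AQHVK--K-TKSELDVQQAQ--RGH-V
LTPGIGRSDEELVSSPKYFLAIDKLSE-LNVGQTQS-GCSGVKLLEV-DVPNK-R-L--E
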