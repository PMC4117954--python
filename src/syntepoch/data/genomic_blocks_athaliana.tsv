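# Ancestral Brassicaceae genomic blocks (A-X) on the A. thaliana genome,
# as refined intervals of AGI locus codes. ak = ancestral karyotype chromosome.
label	ak	start_locus	end_locus
A	1	At1g01010	At1g19840
B	1	At1g19850	At1g37130
C	1	At1g43020	At1g56190
D	2	At1g64670	At1g56210
E	2	At1g64960	At1g80950
F	3	At3g01015	At3g25520
G	3	At2g05170	At2g07690
H	3	At2g10940	At2g20900
I	4	At2g20920	At2g31035
J	4	At2g31040	At2g48150
K	5	At2g01060	At2g05160
L	5	At3g25540	At3g32960
M	5	At3g42180	At3g50940
N	5	At3g50950	At3g63530
O	6	At4g00026	At4g05450
P	6	At4g07390	At4g12620
Q	6	At5g30510	At5g23010
R	6	At5g23000	At5g01010
S	7	At5g42110	At5g32470
T	7	At4g12700	At4g16240
U	7	At4g16250	At4g40100
V	8	At5g42130	At5g47810
W	8	At5g47820	At5g60800
X	8	At5g60805	At5g67640
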