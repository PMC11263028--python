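# RNA-RNA duplex nearest-neighbor free energy parameters, dG37 (kcal/mol).
# Watson-Crick stack values follow Xia et al. (1998); wobble-containing and
# loop values are approximate, in the spirit of Mathews et al. (1999).
# STACK x1 x2 y1 y2 dg  means the stack 5'-x1 x2-3' paired with 3'-y1 y2-5',
# i.e. base pairs (x1:y1) and (x2:y2).
# LOOP n dg: initiation penalty for a bulge/internal loop with n unpaired bases total.
# ASYM dg: penalty per unit of loop asymmetry |n1-n2| (capped at 3.0 total).
# INIT dg: duplex initiation penalty.
INIT	4.09
ASYM	0.50
STACK	A	A	U	U	-0.93
STACK	A	U	U	A	-1.10
STACK	A	C	U	G	-2.24
STACK	A	G	U	C	-2.08
STACK	A	G	U	U	-0.80
STACK	A	U	U	G	-0.80
STACK	U	A	A	U	-1.33
STACK	U	U	A	A	-0.93
STACK	U	C	A	G	-2.35
STACK	U	G	A	C	-2.11
STACK	U	G	A	U	-0.80
STACK	U	U	A	G	-0.80
STACK	C	A	G	U	-2.11
STACK	C	U	G	A	-2.08
STACK	C	C	G	G	-3.26
STACK	C	G	G	C	-2.36
STACK	C	G	G	U	-1.40
STACK	C	U	G	G	-1.40
STACK	G	A	C	U	-2.35
STACK	G	U	C	A	-2.24
STACK	G	C	C	G	-3.42
STACK	G	G	C	C	-3.26
STACK	G	G	C	U	-1.40
STACK	G	U	C	G	-1.40
STACK	G	A	U	U	-0.80
STACK	G	U	U	A	-0.80
STACK	G	C	U	G	-1.40
STACK	G	G	U	C	-1.40
STACK	G	G	U	U	-0.50
STACK	G	U	U	G	0.30
STACK	U	A	G	U	-0.80
STACK	U	U	G	A	-0.80
STACK	U	C	G	G	-1.40
STACK	U	G	G	C	-1.40
STACK	U	G	G	U	-0.50
STACK	U	U	G	G	-0.50
LOOP	1	3.80
LOOP	2	2.80
LOOP	3	3.20
LOOP	4	3.60
LOOP	5	4.00
LOOP	6	4.40
LOOP	7	4.60
LOOP	8	4.80
LOOP	9	5.00
LOOP	10	5.20
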