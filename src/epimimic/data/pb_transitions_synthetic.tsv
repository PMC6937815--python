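# SYNTHETIC protein-block transition weights (stand-in table).
# Not the published PDB-survey transition frequencies: derived
# deterministically from the shipped prototype dihedrals as
#   w(x->y) = exp(-o/45) if o < 90 else 0,
# where o is the RMSDA between the 6 dihedrals shared by consecutive
# windows (x angles 3..8 vs y angles 1..6). Rows: preceding PB;
# columns: following PB. A zero weight means the transition is not allowed.
pb	a	b	c	d	e	f	g	h	i	j	k	l	m	n	o	p
a	0.1444	0.2091	0.6450	0.3026	0.3313	0.3777	0.2884	0.1532	0.0000	0.0000	0.1795	0.0000	0.0000	0.0000	0.0000	0.0000
b	0.1771	0.1356	0.2031	0.2461	0.2340	0.2478	0.2753	0.0000	0.0000	0.1441	0.0000	0.1780	0.0000	0.0000	0.0000	0.0000
c	0.0000	0.2357	0.3572	0.6377	0.6863	0.7200	0.2106	0.1894	0.0000	0.1807	0.2024	0.0000	0.0000	0.0000	0.0000	0.0000
d	0.0000	0.2224	0.2534	0.8692	0.8511	0.7038	0.1602	0.1842	0.0000	0.1888	0.1939	0.0000	0.0000	0.0000	0.0000	0.0000
e	0.0000	0.1484	0.0000	0.2045	0.2205	0.2456	0.0000	0.7792	0.0000	0.0000	0.1420	0.0000	0.0000	0.0000	0.0000	0.0000
f	0.0000	0.6342	0.0000	0.2066	0.2254	0.2116	0.0000	0.0000	0.2280	0.1580	0.7657	0.1960	0.0000	0.0000	0.0000	0.0000
g	0.0000	0.0000	0.2087	0.0000	0.0000	0.1613	0.1864	0.3258	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.1947	0.0000
h	0.0000	0.2021	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.8378	0.2390	0.2709	0.1436	0.0000	0.0000	0.0000	0.1598
i	0.4891	0.0000	0.0000	0.1477	0.1445	0.1431	0.1508	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000
j	0.1459	0.1563	0.0000	0.0000	0.1453	0.0000	0.0000	0.0000	0.0000	0.0000	0.1623	0.1776	0.0000	0.0000	0.0000	0.0000
k	0.0000	0.2231	0.0000	0.0000	0.0000	0.0000	0.1863	0.0000	0.1413	0.0000	0.2034	0.9416	0.1931	0.2013	0.0000	0.0000
l	0.0000	0.1455	0.1522	0.0000	0.0000	0.0000	0.3341	0.0000	0.0000	0.0000	0.0000	0.2088	0.7992	0.8040	0.2499	0.2634
m	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.2763	0.0000	0.0000	0.0000	0.0000	0.1962	0.9654	0.8260	0.2436	0.2574
n	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.1914	0.0000	0.0000	0.0000	0.0000	0.0000	0.2532	0.2122	0.9039	0.0000
o	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.1788	0.0000	0.1648	0.0000	0.0000	0.0000	0.2154	0.2268	0.0000	0.8285
p	0.6668	0.0000	0.1915	0.0000	0.0000	0.0000	0.2523	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000	0.1381	0.0000	0.0000
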