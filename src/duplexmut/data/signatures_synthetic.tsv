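# synthetic signature fixture: SYN_A/SYN_B/SYN_C are constructed
# test columns; SMOKE_LIKE and DEAM_LIKE are synthetic stand-ins
# typed after publicly described mutational processes, not COSMIC data
channel	SYN_A	SYN_B	SYN_C	SMOKE_LIKE	DEAM_LIKE
A[C>A]A	0.02976190	0.00000000	0.01053985	0.01944444	0.00000000
A[C>A]C	0.03373016	0.00000000	0.01067689	0.06944444	0.00000000
A[C>A]G	0.03769841	0.00000000	0.01126293	0.01944444	0.00000000
A[C>A]T	0.04166667	0.00000000	0.01010183	0.06944444	0.00000000
C[C>A]A	0.04563492	0.00000000	0.00972135	0.02916667	0.00000000
C[C>A]C	0.04960317	0.00000000	0.01027526	0.10416667	0.00000000
C[C>A]G	0.05357143	0.00000000	0.00993152	0.02916667	0.00000000
C[C>A]T	0.05753968	0.00000000	0.01167095	0.10416667	0.00000000
G[C>A]A	0.06150794	0.00000000	0.00912635	0.01944444	0.00000000
G[C>A]C	0.06547619	0.00000000	0.00997689	0.06944444	0.00000000
G[C>A]G	0.06944444	0.00000000	0.00929774	0.01944444	0.00000000
G[C>A]T	0.07341270	0.00000000	0.01102817	0.06944444	0.00000000
T[C>A]A	0.07738095	0.00000000	0.01022527	0.02916667	0.00000000
T[C>A]C	0.08134921	0.00000000	0.01041871	0.10416667	0.00000000
T[C>A]G	0.08531746	0.00000000	0.01168441	0.02916667	0.00000000
T[C>A]T	0.08928571	0.00000000	0.01086338	0.10416667	0.00000000
A[C>G]A	0.00297619	0.00000000	0.01145383	0.00416667	0.00000000
A[C>G]C	0.00297619	0.00000000	0.01087390	0.00416667	0.00000000
A[C>G]G	0.00297619	0.00000000	0.01038118	0.00416667	0.00000000
A[C>G]T	0.00297619	0.00000000	0.00978993	0.00416667	0.00000000
C[C>G]A	0.00297619	0.00000000	0.01091614	0.00416667	0.00000000
C[C>G]C	0.00297619	0.00000000	0.01065330	0.00416667	0.00000000
C[C>G]G	0.00297619	0.00000000	0.01145109	0.00416667	0.00000000
C[C>G]T	0.00297619	0.00000000	0.01104535	0.00416667	0.00000000
G[C>G]A	0.00297619	0.00000000	0.00987370	0.00416667	0.00000000
G[C>G]C	0.00297619	0.00000000	0.01132811	0.00416667	0.00000000
G[C>G]G	0.00297619	0.00000000	0.01078537	0.00416667	0.00000000
G[C>G]T	0.00297619	0.00000000	0.00951730	0.00416667	0.00000000
T[C>G]A	0.00297619	0.00000000	0.00980255	0.00416667	0.00000000
T[C>G]C	0.00297619	0.00000000	0.01122470	0.00416667	0.00000000
T[C>G]G	0.00297619	0.00000000	0.00933752	0.00416667	0.00000000
T[C>G]T	0.00297619	0.00000000	0.01049891	0.00416667	0.00000000
A[C>T]A	0.00000000	0.09615385	0.01038295	0.00277778	0.01785714
A[C>T]C	0.00000000	0.09081197	0.01002779	0.00277778	0.01785714
A[C>T]G	0.00000000	0.08547009	0.01083424	0.00277778	0.17857143
A[C>T]T	0.00000000	0.08012821	0.01104636	0.00277778	0.01785714
C[C>T]A	0.00000000	0.07478632	0.01074439	0.00277778	0.01785714
C[C>T]C	0.00000000	0.06944444	0.01160395	0.00277778	0.01785714
C[C>T]G	0.00000000	0.06410256	0.01101170	0.00277778	0.17857143
C[C>T]T	0.00000000	0.05876068	0.01140073	0.00277778	0.01785714
G[C>T]A	0.00000000	0.05341880	0.01155868	0.00277778	0.01785714
G[C>T]C	0.00000000	0.04807692	0.00952445	0.00277778	0.01785714
G[C>T]G	0.00000000	0.04273504	0.01137024	0.00277778	0.17857143
G[C>T]T	0.00000000	0.03739316	0.00924358	0.00277778	0.01785714
T[C>T]A	0.00000000	0.03205128	0.01024164	0.00277778	0.01785714
T[C>T]C	0.00000000	0.02670940	0.01068807	0.00277778	0.01785714
T[C>T]G	0.00000000	0.02136752	0.00976816	0.00277778	0.17857143
T[C>T]T	0.00000000	0.01602564	0.01137166	0.00277778	0.01785714
A[T>A]A	0.00000000	0.00000000	0.00991547	0.00000000	0.00000000
A[T>A]C	0.00000000	0.00000000	0.00986879	0.00000000	0.00000000
A[T>A]G	0.00000000	0.00000000	0.01066014	0.00000000	0.00000000
A[T>A]T	0.00000000	0.00000000	0.01044957	0.00000000	0.00000000
C[T>A]A	0.00000000	0.00000000	0.00924290	0.00000000	0.00000000
C[T>A]C	0.00000000	0.00000000	0.01092602	0.00000000	0.00000000
C[T>A]G	0.00000000	0.00000000	0.00955565	0.00000000	0.00000000
C[T>A]T	0.00000000	0.00000000	0.00962805	0.00000000	0.00000000
G[T>A]A	0.00000000	0.00000000	0.00921709	0.00000000	0.00000000
G[T>A]C	0.00000000	0.00000000	0.01095677	0.00000000	0.00000000
G[T>A]G	0.00000000	0.00000000	0.01048254	0.00000000	0.00000000
G[T>A]T	0.00000000	0.00000000	0.01005196	0.00000000	0.00000000
T[T>A]A	0.00000000	0.00000000	0.00914210	0.00000000	0.00000000
T[T>A]C	0.00000000	0.00000000	0.01011114	0.00000000	0.00000000
T[T>A]G	0.00000000	0.00000000	0.01107027	0.00000000	0.00000000
T[T>A]T	0.00000000	0.00000000	0.00993759	0.00000000	0.00000000
A[T>C]A	0.00000000	0.00641026	0.00942128	0.00000000	0.00446429
A[T>C]C	0.00000000	0.00641026	0.01106216	0.00000000	0.00446429
A[T>C]G	0.00000000	0.00641026	0.01044371	0.00000000	0.00446429
A[T>C]T	0.00000000	0.00641026	0.01012864	0.00000000	0.00446429
C[T>C]A	0.00000000	0.00641026	0.00918044	0.00000000	0.00446429
C[T>C]C	0.00000000	0.00641026	0.01076326	0.00000000	0.00446429
C[T>C]G	0.00000000	0.00641026	0.00947639	0.00000000	0.00446429
C[T>C]T	0.00000000	0.00641026	0.01009095	0.00000000	0.00446429
G[T>C]A	0.00000000	0.00641026	0.00985780	0.00000000	0.00446429
G[T>C]C	0.00000000	0.00641026	0.01174815	0.00000000	0.00446429
G[T>C]G	0.00000000	0.00641026	0.01020676	0.00000000	0.00446429
G[T>C]T	0.00000000	0.00641026	0.01066134	0.00000000	0.00446429
T[T>C]A	0.00000000	0.00641026	0.01023947	0.00000000	0.00446429
T[T>C]C	0.00000000	0.00641026	0.00944534	0.00000000	0.00446429
T[T>C]G	0.00000000	0.00641026	0.01044500	0.00000000	0.00446429
T[T>C]T	0.00000000	0.00641026	0.01039603	0.00000000	0.00446429
A[T>G]A	0.00000000	0.00000000	0.01046870	0.00000000	0.00000000
A[T>G]C	0.00000000	0.00000000	0.00944517	0.00000000	0.00000000
A[T>G]G	0.00000000	0.00000000	0.01060130	0.00000000	0.00000000
A[T>G]T	0.00000000	0.00000000	0.01002834	0.00000000	0.00000000
C[T>G]A	0.00000000	0.00000000	0.01174650	0.00000000	0.00000000
C[T>G]C	0.00000000	0.00000000	0.01011667	0.00000000	0.00000000
C[T>G]G	0.00000000	0.00000000	0.01123582	0.00000000	0.00000000
C[T>G]T	0.00000000	0.00000000	0.01084261	0.00000000	0.00000000
G[T>G]A	0.00000000	0.00000000	0.01091717	0.00000000	0.00000000
G[T>G]C	0.00000000	0.00000000	0.00971533	0.00000000	0.00000000
G[T>G]G	0.00000000	0.00000000	0.01145908	0.00000000	0.00000000
G[T>G]T	0.00000000	0.00000000	0.01046989	0.00000000	0.00000000
T[T>G]A	0.00000000	0.00000000	0.00990126	0.00000000	0.00000000
T[T>G]C	0.00000000	0.00000000	0.01115212	0.00000000	0.00000000
T[T>G]G	0.00000000	0.00000000	0.00986539	0.00000000	0.00000000
T[T>G]T	0.00000000	0.00000000	0.01069892	0.00000000	0.00000000
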