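# Domain-architecture input template (synthetic placeholder boundaries).
#
# To analyse a real MyBP-C protein, replace every start_aa/end_aa below with
# the domain boundaries from the protein's UniProt entry (Family & Domains →
# "Domain" and "Region" features; use the 1-based inclusive positions as
# printed), set length_aa to the canonical sequence length, and keep one row
# per module in N→C order.  Classes: Ig (I-set immunoglobulin-like domains),
# Fn3 (fibronectin type III: C6, C7, C9), PA_rich (Pro/Ala-rich linker),
# M_domain (the phosphorylatable MyBP-C motif between C1 and C2), loop
# (e.g. the cardiac 28-aa insertion inside C5 — split C5 into flanking rows
# around it, intervals must not overlap), linker (explicit gap, optional —
# unnamed gaps are counted as linker automatically).
#
# The boundaries below are round-number placeholders for a cardiac-like
# layout (C0 first), NOT UniProt values.
# protein=cardiac-MyBP-C-template length_aa=1274
name	class	start_aa	end_aa
C0	Ig	1	100
PA	PA_rich	106	145
C1	Ig	151	250
M	M_domain	261	360
C2	Ig	366	465
C3	Ig	471	570
C4	Ig	576	675
C5	Ig	681	790
C6	Fn3	796	895
C7	Fn3	901	1000
C8	Ig	1006	1105
C9	Fn3	1111	1210
C10	Ig	1216	1274
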