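# TTN recessive-myopathy cohort fixture: 30 patients / 26 families, each
# combining a candidate missense variant (in 2 families an in-cis missense
# pair) with a truncating variant (TTNtv) in trans.
# psi_note transcribes the published exon-usage annotations:
#   decreasing = "(PSI decreasing from prenatal to postnatal)";
#   low_both   = "(low PSI both in pre and postnatal muscles)".
# AlphaMissense scores, MAFs and exon numbers that are not individually
# published are filled with representative synthetic placeholder values
# consistent with the cohort inclusion thresholds (missense MAF < 0.010,
# score >= 0.792); empty maf = absent from gnomAD.
family	patient	role	cdna	protein	exon	consequence	am_score	maf	hom_count	psi_prenatal	psi_postnatal	phase	onset	psi_note
F1	P1	missense	c.21068A>C	p.(Gln7023Pro)	75	missense	0.81	0.000005578	0	90	88	confirmed_trans	congenital
F1	P1	ttntv	c.24729C>A	p.(Cys8243Ter)	86	nonsense			0	94	86	confirmed_trans	congenital
F1	P2	missense	c.21068A>C	p.(Gln7023Pro)	75	missense	0.81	0.000005578	0	90	88	confirmed_trans	congenital
F1	P2	ttntv	c.24729C>A	p.(Cys8243Ter)	86	nonsense			0	94	86	confirmed_trans	congenital
F2	P1	missense	c.21068A>C	p.(Gln7023Pro)	75	missense	0.81	0.000005578	0	90	88	confirmed_trans	congenital
F2	P1	ttntv	c.55351C>T	p.(Arg18451Ter)	287	nonsense			0	94	87	confirmed_trans	congenital
F3	P1	missense	c.21068A>C	p.(Gln7023Pro)	75	missense	0.81	0.000005578	0	90	88	confirmed_trans	congenital
F3	P1	ttntv	c.68575_68576dup	p.(Ile22861SerfsTer14)	324	frameshift			0	93	86	confirmed_trans	congenital
F4	P1	missense	c.21068A>C	p.(Gln7023Pro)	75	missense	0.81	0.000005578	0	90	88	presumed_trans	congenital
F4	P1	ttntv	c.61876C>T	p.(Arg20626Ter)	305	nonsense			0	96	91	presumed_trans	congenital
F5	P1	missense	c.21068A>C	p.(Gln7023Pro)	75	missense	0.81	0.000005578	0	90	88	confirmed_trans	congenital
F5	P1	ttntv	c.26173_26174delAC	p.(Thr8725LeufsTer19)	91	frameshift			0	95	85	confirmed_trans	congenital
F6	P1	missense	c.21068A>C	p.(Gln7023Pro)	75	missense	0.81	0.000005578	0	90	88	confirmed_trans	congenital
F6	P1	ttntv	c.32092C>T	p.(Arg10698Ter)	126	nonsense			0	89	70	confirmed_trans	congenital
F7	P1	missense	c.14486A>C	p.(Gln4829Pro)	51	missense	0.90	0.0001909	0	97	94	confirmed_trans	adult
F7	P1	ttntv	c.42472dup	p.(Thr14158AsnfsTer7)	232	frameshift			0	97	91	confirmed_trans	adult
F8	P1	missense	c.14486A>C	p.(Gln4829Pro)	51	missense	0.90	0.0001909	0	97	94	confirmed_trans	adult
F8	P1	ttntv	c.26028del	p.(Trp8676CysfsTer16)	91	frameshift			0	95	85	confirmed_trans	adult
F8	P2	missense	c.14486A>C	p.(Gln4829Pro)	51	missense	0.90	0.0001909	0	97	94	confirmed_trans	adult
F8	P2	ttntv	c.26028del	p.(Trp8676CysfsTer16)	91	frameshift			0	95	85	confirmed_trans	adult
F9	P1	missense	c.25039T>C	p.(Ser8347Pro)	87	missense	0.95	0.00000062	0	94	86	confirmed_trans	congenital
F9	P1	ttntv	c.76109_76110delTA	p.(Ile25370ArgfsTer6)	327	frameshift			0	97	93	confirmed_trans	congenital
F10	P1	missense	c.88658T>G	p.(Leu29553Arg)	333	missense	0.93	0.00001	0	93	84	confirmed_trans	congenital
F10	P1	ttntv	c.36285C>G	p.(His12095Gln)	170	splice			0	57	10	confirmed_trans	congenital	decreasing
F11	P1	missense	c.23035T>G	p.(Tyr7679Asp)	80	missense	0.88		0	96	85	confirmed_trans	congenital
F11	P1	ttntv	c.47399_47402dup	p.(Ser15802AspfsTer14)	254	frameshift			0	97	94	confirmed_trans	congenital
F12	P1	missense	c.41124T>G	p.(Cys13708Trp)	226	missense	0.91	0.000002	0	97	94	confirmed_trans	congenital
F12	P1	ttntv	c.29245C>T	p.(Gln9749Ter)	103	nonsense			0	97	95	confirmed_trans	congenital
F13	P1	missense	c.84523T>C	p.(Trp28175Arg)	327	missense	0.97		0	97	93	confirmed_trans	congenital
F13	P1	ttntv	c.57215del	p.(Gly19072GlufsTer12)	294	frameshift			0	93	87	confirmed_trans	congenital
F14	P1	missense	c.85302T>A	p.(Asn28434Lys)	327	missense	0.89	0.000004	0	97	93	confirmed_trans	congenital
F14	P1	missense	c.83281G>C	p.(Val27761Leu)	327	missense	0.87	0.0002	0	97	93	confirmed_trans	congenital
F14	P1	ttntv	c.103360del	p.(Glu34454AsnfsTer3)	359	frameshift			0	94	94	confirmed_trans	congenital
F15	P1	missense	c.99518G>A	p.(Cys33173Tyr)	356	missense	0.94	0.000008	0	96	94	confirmed_trans	congenital
F15	P1	ttntv	c.68885_68888dup	p.(Ile22964TyrfsTer8)	325	frameshift			0	92	87	confirmed_trans	congenital
F15	P2	missense	c.99518G>A	p.(Cys33173Tyr)	356	missense	0.94	0.000008	0	96	94	confirmed_trans	congenital
F15	P2	ttntv	c.68885_68888dup	p.(Ile22964TyrfsTer8)	325	frameshift			0	92	87	confirmed_trans	congenital
F16	P1	missense	c.29800T>C	p.(Trp9934Arg)	106	missense	0.96		0	97	95	confirmed_trans	congenital
F16	P1	ttntv	c.91669C>T	p.(Arg30557Ter)	338	nonsense			0	91	83	confirmed_trans	congenital
F17	P1	missense	c.102200C>A	p.(Ala34067Asp)	359	missense	0.86	0.00002	0	94	94	confirmed_trans	congenital
F17	P1	ttntv	c.37246del	p.(Ser12416ArgfsTer531)	181	frameshift			0	7	1	confirmed_trans	congenital	decreasing
F18	P1	missense	c.14588G>A	p.(Gly4863Glu)	51	missense	0.85	0.00003	0	58	39	confirmed_trans	congenital	decreasing
F18	P1	ttntv	c.67_81delinsCTCCAGTGGTAGTAC	p.(Ala23_Ala27delinsLeuGlnTrpTer)	2	nonsense			0	100	100	confirmed_trans	congenital
F19	P1	missense	c.98171T>C	p.(Leu32724Pro)	353	missense	0.92		0	95	91	confirmed_trans	congenital
F19	P1	ttntv	c.37543+1G>T		184	splice			0	21	22	confirmed_trans	congenital	low_both
F19	P2	missense	c.98171T>C	p.(Leu32724Pro)	353	missense	0.92		0	95	91	confirmed_trans	congenital
F19	P2	ttntv	c.37543+1G>T		184	splice			0	21	22	confirmed_trans	congenital	low_both
F20	P1	missense	c.76439G>C	p.(Arg25480Pro)	327	missense	0.93	0.00001	0	97	93	confirmed_trans	congenital
F20	P1	ttntv	c.27435G>A	p.(Trp9145Ter)	96	nonsense			0	98	94	confirmed_trans	congenital
F21	P1	missense	c.53348T>C	p.(Leu17783Pro)	279	missense	0.90		0	97	92	confirmed_trans	congenital
F21	P1	ttntv	c.39109G>T	p.(Glu13037Ter)	203	nonsense			0	35	21	confirmed_trans	congenital	decreasing
F22	P1	missense	c.100237T>C	p.(Trp33413Arg)	358	missense	0.95	0.000006	0	90	89	confirmed_trans	childhood
F22	P1	ttntv	c.7856-1G>A		33	splice			0	99	96	confirmed_trans	childhood
F23	P1	missense	c.106919T>C	p.(Leu35640Pro)	361	missense	0.88	0.00004	0	94	94	confirmed_trans	childhood
F23	P1	ttntv	c.91476T>A	p.(Tyr30492Ter)	337	nonsense			0	92	84	confirmed_trans	childhood
F24	P1	missense	c.25006T>C	p.(Cys8336Arg)	87	missense	0.97		0	94	86	confirmed_trans	childhood
F24	P1	ttntv	c.33938dup	p.(Glu11314ArgfsTer24)	146	frameshift			0	67	46	confirmed_trans	childhood	decreasing
F25	P1	missense	c.99400T>A	p.(Trp33134Arg)	356	missense	0.96	0.000003	0	96	94	confirmed_trans	childhood
F25	P1	missense	c.54142T>C	p.(Ser18048Pro)	281	missense	0.9851	0.000009	0	97	91	confirmed_trans	childhood
F25	P1	ttntv	c.83416C>T	p.(Arg27806Ter)	327	nonsense			0	97	93	confirmed_trans	childhood
F26	P1	missense	c.72146T>C	p.(Leu24049Pro)	327	missense	0.989	0.0012	4	97	93	confirmed_trans	adult
F26	P1	ttntv	c.62251G>T	p.(Glu20751Ter)	305	nonsense			0	96	91	confirmed_trans	adult
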