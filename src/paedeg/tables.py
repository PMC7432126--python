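"""Printed reference tables for the phthalate (PAE) biodegradability study.

These are the published input data of the workflow: enzyme-docking scores for
17 PAEs against three plasticizer-degrading enzymes (phthalate dioxygenase
reductase 2PIA, esterase 2ZYI, carboxylesterase 3CN7), the 30-derivative
prediction table for diethyl phthalate (DEP), the DFT/POP property table of
the short-listed derivatives, and the degradation-pathway energy barriers.
Docking scores, DFT energies/barriers and property predictions are upstream
inputs here, not quantities this package computes.

Each ``TABLE*`` constant is a TSV string; the ``load_table*`` helpers return
typed :class:`pandas.DataFrame` objects.
"""

from __future__ import annotations

import io

import pandas as pd

#: Docking scores of 17 PAEs vs the three degrading enzymes, with the
#: published train (a) / test (b) / template (*) annotation.
TABLE1_SCORES = """\
compound	role	2PIA	2ZYI	3CN7
BBP	train	7.070	1.908	5.116
DAP	train	5.918	5.461	5.275
DBP	test	5.754	5.551	6.047
DEP	train	5.574	4.711	3.548
DHP	train	7.455	7.221	6.964
DIBP	train	4.824	5.081	5.006
DIHP	train	8.634	10.570	7.870
DIHXP	none	7.462	10.548	6.660
DIPP	train	6.313	5.916	6.061
DIPRP	train	5.339	4.609	5.885
DMEP	test	7.085	4.088	6.876
DMP	train	3.293	4.624	3.940
DNOP	train	10.420	4.797	8.333
DPP	train	5.484	4.970	6.313
DPRP	test	6.273	6.681	4.746
DTDP	train	9.112	13.722	8.584
DUP	template	11.595	14.334	8.561
"""

#: Published derived columns of the same table: range-normalized values and
#: the entropy-weighted composite Z (all printed at 3 d.p.).
TABLE1_DERIVED = """\
compound	Y_2PIA	Y_2ZYI	Y_3CN7	Z
BBP	0.509	0.100	0.380	0.323
DAP	0.385	0.357	0.409	0.380
DBP	0.367	0.364	0.547	0.408
DEP	0.347	0.303	0.100	0.272
DHP	0.551	0.485	0.711	0.564
DIBP	0.266	0.330	0.361	0.313
DIHP	0.679	0.727	0.872	0.743
DIHXP	0.552	0.726	0.656	0.643
DIPP	0.427	0.390	0.549	0.442
DIPRP	0.322	0.296	0.518	0.358
DMEP	0.511	0.258	0.695	0.459
DMP	0.100	0.297	0.170	0.191
DNOP	0.873	0.309	0.955	0.679
DPP	0.338	0.322	0.594	0.393
DPRP	0.423	0.446	0.314	0.406
DTDP	0.731	0.956	1.000	0.880
DUP	1.000	1.000	0.996	0.999
"""

#: Published entropy / difference-coefficient / weight footer rows (per
#: endpoint, printed at 3 d.p. resp. 2 d.p. percent).
TABLE1_FOOTER = {
    "E": (1.799, 1.792, 1.497),
    "H": (0.799, 0.792, 0.497),
    "W_pct": (38.28, 37.93, 23.79),
}

#: DEP derivative predictions: composite biodegradability and per-enzyme
#: docking scores with published change rates and ratio triples.  The DEP
#: row carries the parent baselines at the precision used for the printed
#: change rates.  Missing ratios are printed as "-" in the source.
TABLE3_DERIVATIVES = """\
id	substituent	Z	Z_rate	2PIA	2PIA_rate	2ZYI	2ZYI_rate	3CN7	3CN7_rate	ratio
DEP		0.27		5.57		4.71		3.55
DEP-1	H1-CH3	0.293	8.52	5.637	1.20	5.232	11.08	4.319	21.66
DEP-2	H1-CH2CH3	0.311	15.19	5.762	3.45	5.353	13.65	4.329	21.94
DEP-3	H1-CH(CH3)2	0.328	21.48	5.876	5.49	5.397	14.59	4.399	23.92
DEP-4	H1-C(CH3)3	0.349	29.26	5.976	7.29	5.673	20.45	4.360	22.82
DEP-5	C1-CH3	0.269	-0.37	5.500	-1.26	4.827	2.48	4.262	20.06
DEP-6	C1-OH	0.228	-15.56	4.828	-13.32	4.838	2.72	4.224	18.99
DEP-7	C1-H	0.272	0.74	5.059	-9.17	4.784	1.57	4.372	23.15
DEP-8	C1-CN	0.255	-5.56	5.266	-5.46	4.874	3.48	4.172	17.52
DEP-9	C1-NH2	0.225	-16.67	4.967	-10.83	4.677	-0.70	4.327	21.89
DEP-10	C1-CHO	0.255	-5.56	4.938	-11.35	5.077	7.79	4.113	15.86
DEP-11	C2-OH	0.249	-7.78	5.658	1.58	4.594	-2.46	4.290	20.85
DEP-12	C2-CHO	0.262	-2.96	5.737	3.00	4.871	3.42	4.282	20.62
DEP-13	C2-COOH	0.269	-0.37	5.892	5.78	4.921	4.48	4.312	21.46
DEP-14	C2-NH2	0.256	-5.19	5.504	-1.18	4.911	4.27	4.199	18.28
DEP-15	C2-COCH3	0.289	7.04	6.109	9.68	4.969	5.50	4.378	23.32
DEP-16	C2-CONH2	0.235	-12.96	5.755	3.32	4.776	1.40	4.436	24.96
DEP-17	C2-(OH)2	0.267	-1.11	5.484	-1.54	5.495	16.67	4.170	17.46
DEP-18	C2-(CHO)2	0.267	-1.11	5.409	-2.89	5.730	21.66	4.131	16.37
DEP-19	C2-(COOH)2	0.284	5.19	5.621	0.92	5.826	23.69	4.119	16.03
DEP-20	C2-(NH2)2	0.259	-4.07	5.444	-2.26	5.434	15.37	4.295	20.99
DEP-21	C2-(COCH3)2	0.310	14.81	5.799	4.11	6.015	27.71	4.188	17.97
DEP-22	C2-(CONH2)2	0.261	-3.33	5.362	-3.73	5.946	26.24	4.175	17.61
DEP-23	H1-CH3-C2-COCH3	0.357	32.22	6.317	13.41	5.547	17.77	4.198	18.25	27.13:35.95:36.92
DEP-24	H1-CH2CH3-C2-COCH3	0.377	39.63	6.453	15.85	5.725	21.55	4.169	17.44	28.91:39.30:31.80
DEP-25	H1-CH(CH3)2-C2-COCH3	0.389	44.07	6.565	17.86	5.708	21.19	4.200	18.31	31.14:36.94:31.92
DEP-26	H1-C(CH3)3-C2-COCH3	0.406	50.37	6.725	20.74	5.787	22.87	4.282	20.62	32.29:35.60:32.11
DEP-27	H1-CH3-C2-CONH2	0.333	23.33	6.077	9.10	5.778	22.68	4.129	16.31	18.93:47.15:33.92
DEP-28	H1-CH2CH3-C2-CONH2	0.343	27.04	6.151	10.43	5.898	25.22	4.130	16.34	20.06:48.51:31.42
DEP-29	H1-CH(CH3)2-C2-CONH2	0.356	31.85	6.263	12.44	5.879	24.82	4.144	16.73	23.04:45.97:30.99
DEP-30	H1-C(CH3)3-C2-CONH2	0.370	37.04	6.382	14.58	5.953	26.39	4.230	19.15	24.25:43.89:31.86
"""

#: DFT stability and persistent-organic-pollutant (POP) screening properties
#: of DEP and the eight double-substituted derivatives, with published change
#: rates (see the screening module for the per-column sign conventions).
TABLE5_PROPERTIES = """\
id	energy_au	energy_rate	gap_ev	freq_cm1	logLC50	logLC50_rate	logBCF	BCF	logt12	logt12_rate	logKOA	logKOA_rate
DEP	-766.62		5.32	24.02	1.100		1.264	18.37	3.156		7.505
DEP-23	-919.26	-19.91	5.15	15.09	0.781	29.00	1.879	75.68	3.271	-3.64	8.540	13.79
DEP-24	-958.57	-25.04	5.16	18.09	0.744	32.36	1.992	98.17	3.250	-2.98	8.546	13.87
DEP-25	-997.89	-30.17	5.14	17.65	0.737	33.00	2.041	109.90	3.230	-2.34	8.563	14.10
DEP-26	-1037.20	-35.30	5.06	15.38	0.672	38.91	2.116	130.62	3.215	-1.87	8.766	16.80
DEP-27	-935.32	-22.01	5.00	19.32	1.070	2.73	1.569	37.07	3.386	-7.29	8.329	10.98
DEP-28	-974.64	-27.13	4.97	16.33	1.047	4.82	1.600	39.81	3.378	-7.03	8.352	11.29
DEP-29	-1013.95	-32.26	4.96	16.24	1.038	5.64	1.653	44.98	3.357	-6.37	8.374	11.58
DEP-30	-1053.26	-37.39	4.94	15.99	0.923	16.09	1.716	52.00	3.349	-6.12	8.489	13.11
"""

#: Microbial degradation pathway step barriers (kJ/mol).  Path1 is the
#: Gram-negative (4,5-dioxygenation) route, Path2 the Gram-positive
#: (3,4-dihydroxylation) route.
TABLE6_STEPS = """\
compound	path	step	reactant	product	barrier
DEP	Path1	1	DEP	M0-1	27.57
DEP	Path1	2	M0-1	M0-2	15.75
DEP	Path1	3	M0-2	M0-3	53.82
DEP	Path1	4	M0-3	M0-5	30.19
DEP	Path2	1	DEP	M0-1	27.57
DEP	Path2	2	M0-1	M0-2	15.75
DEP	Path2	3	M0-2	M0-4	68.79
DEP	Path2	4	M0-4	M0-5	27.57
DEP-27	Path1	1	DEP-27	M1-1	28.88
DEP-27	Path1	2	M1-1	M1-2	13.92
DEP-27	Path1	3	M1-2	M1-3	56.97
DEP-27	Path1	4	M1-3	M1-5	13.39
DEP-27	Path2	1	DEP-27	M1-1	28.88
DEP-27	Path2	2	M1-1	M1-2	13.92
DEP-27	Path2	3	M1-2	M1-4	72.99
DEP-27	Path2	4	M1-4	M1-5	11.29
DEP-28	Path1	1	DEP-28	M2-1	24.94
DEP-28	Path1	2	M2-1	M2-2	15.67
DEP-28	Path1	3	M2-2	M2-3	56.97
DEP-28	Path1	4	M2-3	M2-5	13.39
DEP-28	Path2	1	DEP-28	M2-1	24.94
DEP-28	Path2	2	M2-1	M2-2	15.67
DEP-28	Path2	3	M2-2	M2-4	72.99
DEP-28	Path2	4	M2-4	M2-5	11.29
DEP-29	Path1	1	DEP-29	M3-1	17.07
DEP-29	Path1	2	M3-1	M3-2	12.34
DEP-29	Path1	3	M3-2	M3-3	56.97
DEP-29	Path1	4	M3-3	M3-5	13.39
DEP-29	Path2	1	DEP-29	M3-1	17.07
DEP-29	Path2	2	M3-1	M3-2	12.34
DEP-29	Path2	3	M3-2	M3-4	72.99
DEP-29	Path2	4	M3-4	M3-5	11.29
"""

#: Published Table 6 aggregates: per-path total barriers, per-path change
#: rates vs DEP and the published "total change rate" (sum over paths).
TABLE6_AGGREGATES = """\
compound	path	total	rate	total_rate
DEP	Path1	127.33
DEP	Path2	139.68
DEP-27	Path1	113.16	-11.13	-20.15
DEP-27	Path2	127.07	-9.02	-20.15
DEP-28	Path1	110.98	-12.84	-23.42
DEP-28	Path2	124.90	-10.58	-23.42
DEP-29	Path1	99.77	-21.65	-30.26
DEP-29	Path2	113.68	-18.61	-30.26
"""


def _read(tsv: str) -> pd.DataFrame:
    return pd.read_csv(io.StringIO(tsv), sep="\t")


def load_table1_scores() -> pd.DataFrame:
    """Raw docking scores with the train/test/template role column."""
    return _read(TABLE1_SCORES)


def load_table1_derived() -> pd.DataFrame:
    """Published normalized values and composite scores (3 d.p.)."""
    return _read(TABLE1_DERIVED)


def load_table3() -> pd.DataFrame:
    """DEP derivative predictions with published change rates and ratios."""
    return _read(TABLE3_DERIVATIVES)


def load_table5() -> pd.DataFrame:
    """DFT / POP properties of DEP and derivatives with change rates."""
    return _read(TABLE5_PROPERTIES)


def load_table6_steps() -> pd.DataFrame:
    """Pathway step barriers in long format."""
    return _read(TABLE6_STEPS)


def load_table6_aggregates() -> pd.DataFrame:
    """Published pathway totals and change rates."""
    return _read(TABLE6_AGGREGATES)
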