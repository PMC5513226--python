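"""Published per-bird prenesting summaries for the two study populations.

These are the per-female summary records published for 21 Rio Grande
(north-central Texas, 2012-2013) and 23 Eastern (west-central Louisiana,
2014) wild turkey females — the only deposited data for the study — in the
pipeline's summary-table schema: days of prenesting coverage, nest fate,
nest membership (In/Out) and area (ha) of the 50/95/99% prenesting-range
isopleths, mean (SD) and minimum nest distance (m) over all prenesting
fixes, and the day before laying of closest approach.

A minimum distance of ``<1`` is a censored entry: it is parsed as the bound
with ``min_censored=True`` and excluded from mean recomputation.
"""

from __future__ import annotations

import io

import pandas as pd

RIO_GRANDE_TABLE = """\
bird_id	days_of_prenest	fate	in_50	area_50_ha	in_95	area_95_ha	in_99	area_99_ha	mean_m	sd_m	min_m	day_closest
8058	45	fail	In	99.44	In	599.71	In	859.53	385.82	292.10	6.47	3
A587('12)	33	fail	Out	164.28	Out	592.93	Out	2760.9	1149.99	496.98	355.37	18
A587('13)	36	fail	Out	55.28	In	850.06	In	1347.6	672.81	419.41	32.06	5
A590	45	fail	Out	62.74	In	669.23	In	1121.2	586.05	430.03	52.30	30
8009	44	fail	Out	1170.7	In	5437.83	In	7461.24	3267.51	1459.30	368.22	2
8013	45	fail	Out	198.69	In	920.86	In	1338.1	1931.40	565.44	24.07	2
8016	45	fail	Out	102.96	In	673.65	In	1061.6	829.89	382.81	30.22	7
8021	46	fail	In	165.44	In	597.1	In	788.68	755.88	398.89	3.51	2
8024	44	fail	Out	169.19	In	649.88	In	852.21	719.25	501.32	64.88	13
8026	45	fail	Out	143.73	In	595.19	In	812.9	689.30	320.36	109.37	12
8028	46	fail	Out	178.09	In	983.36	In	1390	1238.30	598.61	185.07	3
8029	43	fail	In	1437.05	In	3237.7	In	20417.14	6859.76	4249.15	36.04	12
21270	39	fail	Out	299.19	In	1772	In	2780.9	1149.74	906.23	24.03	2
8061	45	fail	In	1844.2	In	16251.03	In	24134.74	3452.15	5812.75	88.56	33
8063	45	fail	Out	125.97	In	1177.8	In	1630.4	3398.78	1489.65	2.77	2
8503	44	fail	Out	72.38	In	414.46	In	619.38	893.82	470.09	2.51	2
A588	45	success	Out	105.93	In	520.24	In	783.02	702.86	488.21	29.73	4
A589	25	fail	Out	60.97	Out	291.09	Out	447.92	1301.07	428.38	662.18	3
A591	45	success	Out	116.69	In	590.77	In	924.31	706.44	456.13	18.93	1
8134	41	fail	Out	85.6	In	625.05	In	1036.4	1563.82	642.83	139.50	3
8094	44	fail	Out	104.99	Out	658.12	Out	971.9	2102.48	395.29	1259.96	1
"""

EASTERN_TABLE = """\
bird_id	days_of_prenest	fate	in_50	area_50_ha	in_95	area_95_ha	in_99	area_99_ha	mean_m	sd_m	min_m	day_closest
48	45	fail	Out	157.44	Out	1251.9	Out	1506.5	4231.81	1283.99	1359.08	3
50	45	fail	Out	49.17	In	427	In	846.64	384.35	495.99	31.04	6
51	46	fail	Out	510.94	In	3217.7	In	4681	4315.20	2742.93	156.31	4
132	45	fail	In	429.72	In	2050.2	In	2846.2	1890.91	1986.24	34.48	5
133	45	fail	Out	115.05	Out	433.37	Out	603.28	1210.52	552.76	367.19	5
134	45	fail	Out	162.96	Out	1109.5	In	1610.6	4502.91	1550.50	83.75	1
135	45	fail	Out	489.29	In	2347.9	In	3573	3424.63	2359.39	99.34	8
136	45	fail	Out	230.73	In	1079.8	In	1556.1	1349.59	751.92	192.39	7
369	45	fail	In	341.75	In	1625.8	In	2235.4	1101.39	1132.95	51.12	2
371	45	fail	Out	274.24	Out	1213.1	In	1850.5	1535.42	734.1937	503.43	9
372	45	fail	Out	275.82	In	1078.8	In	1460.8	1157.97	701.54	40.03	29
656	45	fail	Out	532.92	In	2090.1	In	2790.9	1678.61	832.08	4.95	2
657	45	fail	Out	69.67	In	610.64	In	939.36	778.53	593.07	112.53	1
658	45	fail	Out	124.62	In	757.84	In	1084.3	1259.55	419.53	205.37	7
660	45	fail	In	269.76	In	1010.6	In	1409.7	668.63	378.85	53.29	32
661	45	fail	Out	85.32	In	673.81	In	1135.1	1464.33	513.21	51.07	1
662	45	success	Out	36.99	Out	284.86	Out	423.65	1511.46	315.58	824.96	44
663	45	fail	Out	114.97	In	849.53	In	1305.7	4208.09	1408.03	175.35	4
667	45	fail	Out	311.37	In	2012.5	In	3008.9	1626.79	676.84	112.42	44
710	45	fail	Out	43.78	Out	363.07	In	620.35	1904.47	544.77	86.46	2
777	45	fail	Out	73.36	In	380.65	In	522.73	621.78	386.48	<1	5
13210	45	fail	Out	155.37	Out	650.39	Out	899.11	1957.31	645.75	816.38	41
13181	45	success	Out	115.95	In	694.57	In	1045	1776.36	713.76	73.90	4
"""


def load_study_table(subspecies: str) -> pd.DataFrame:
    """Per-bird summary table for ``'rio_grande'`` or ``'eastern'``.

    Censored minimum distances ("<1") become the bound value with
    ``min_censored=True``.
    """
    raw = {"rio_grande": RIO_GRANDE_TABLE, "eastern": EASTERN_TABLE}[subspecies]
    df = pd.read_csv(io.StringIO(raw), sep="\t", dtype=str)
    df["min_censored"] = df["min_m"].str.startswith("<")
    df["min_m"] = df["min_m"].str.lstrip("<").astype(float)
    for col in (
        "days_of_prenest",
        "area_50_ha",
        "area_95_ha",
        "area_99_ha",
        "mean_m",
        "sd_m",
        "day_closest",
    ):
        df[col] = pd.to_numeric(df[col])
    return df
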