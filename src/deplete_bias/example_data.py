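"""Published example filtering tables bundled as package data.

Two read-accounting tables from a saponin/DNase host-DNA-depletion benchmark
on human-associated specimens: one spanning seven biological matrices, each
sequenced untreated (NT) and after 2.5% wt/vol saponin treatment (T), and one
dose series of a single sputum sample across saponin concentrations.  Each
record is (sample, reads produced, high-quality reads, reads retained after
human-read filtering) together with the host-filtered percentage as printed
in the source table — useful as a regression oracle for the accounting
arithmetic and as realistic input for examples.
"""

from __future__ import annotations

from .accounting import ReadAccounting

# (sample_id, reads_produced, high_quality_reads, retained, printed % filtered host)
MATRIX_FILTERING_ROWS: tuple[tuple[str, int, int, int, float], ...] = (
    ("Vaginal-NT", 154_701, 151_193, 4_266, 97.18),
    ("Vaginal-T", 222_202, 211_864, 159_017, 24.94),
    ("Gastric antrum-NT", 101_522, 99_529, 494, 99.50),
    ("Gastric antrum-T", 59_749, 56_936, 251, 99.56),
    ("Gastric body-NT", 136_117, 133_250, 1_214, 99.09),
    ("Gastric body-T", 143_220, 139_737, 199, 99.86),
    ("Saliva-NT", 134_011, 131_338, 30_156, 77.04),
    ("Saliva-T", 225_114, 218_562, 208_893, 4.42),
    ("Skin-NT", 242_037, 233_438, 128_078, 45.13),
    ("Skin-T", 236_997, 227_914, 163_985, 28.05),
    ("Sputum-NT", 77_837, 52_182, 9_776, 81.27),
    ("Sputum-T", 208_337, 203_745, 200_275, 1.70),
    ("Nasopharyngeal-Swab-NT", 78_150, 71_634, 3_613, 94.96),
    ("Nasopharyngeal-Swab-T", 4_184, 4_017, 3_933, 2.09),
)

SPUTUM_DOSE_FILTERING_ROWS: tuple[tuple[str, int, int, int, float], ...] = (
    ("Sputum-0.0125%", 51_453, 48_877, 31_094, 36.38),
    ("Sputum-0.05%", 34_712, 33_795, 31_860, 5.73),
    ("Sputum-0.1%", 41_873, 40_807, 39_754, 2.58),
    ("Sputum-0.5%", 13_420, 13_056, 12_774, 2.16),
    ("Sputum-1.5%", 34_688, 33_633, 32_716, 2.73),
    ("Sputum-2%", 37_528, 36_418, 35_249, 3.21),
    ("Sputum-NT", 38_545, 37_556, 17_595, 53.15),
)


def matrix_accounting() -> list[ReadAccounting]:
    """The seven-matrix treated/untreated table as accounting records."""
    return [ReadAccounting(s, p, hq, r) for s, p, hq, r, _ in MATRIX_FILTERING_ROWS]


def sputum_dose_accounting() -> list[ReadAccounting]:
    """The sputum saponin dose series as accounting records."""
    return [ReadAccounting(s, p, hq, r) for s, p, hq, r, _ in SPUTUM_DOSE_FILTERING_ROWS]
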