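"""Published group summaries for the two MCC-ciliopathy mouse cohorts.

These are the printed per-group statistics (mean, SEM, n) from the
source study's morphometry tables and results text for the CEP164
conditional-knockout cohort (FOXJ1-Cre;CEP164fl/fl vs CEP164fl/fl
littermate controls) and the p73 knockout cohort (p73-/- vs p73+/+).
They are inputs to the table-reproduction harness in :mod:`.stats`:
the package recomputes differences, SEs, CIs and Welch p-values from
them and compares against the printed entries.  All dispersions are
standard errors of the mean as stated in the table footnotes.
"""

from __future__ import annotations

from .stats import GroupSummary

__all__ = [
    "CEP164_MORPHOMETRY",
    "P73_MORPHOMETRY",
    "GROUP_SUMMARIES",
    "PEARSON_VALIDATION",
]

TableRow = tuple[str, GroupSummary, GroupSummary]


def _row(name: str, ctrl: tuple[int, float, float],
         mut: tuple[int, float, float]) -> TableRow:
    return (name,
            GroupSummary("control", ctrl[0], ctrl[1], ctrl[2], kind="SEM"),
            GroupSummary("mutant", mut[0], mut[1], mut[2], kind="SEM"))


#: Baseline in vivo brain-compartment volumes, CEP164 cohort
#: (control N=10 vs conditional knockout N=10).  Volumes mm^3 unless
#: noted; CV = cerebral ventricle.
CEP164_MORPHOMETRY: list[TableRow] = [
    _row("tiv_mm3", (10, 478.1, 5.3), (10, 512.6, 11.5)),
    _row("brain_tissue_mm3", (10, 468.3, 4.7), (10, 471.8, 6.2)),
    _row("cv_volume_mm3", (10, 5.4, 0.5), (10, 35.6, 7.6)),
    _row("cv_fraction_of_tiv_pct", (10, 1.1, 0.1), (10, 6.7, 1.2)),
    _row("olfactory_bulb_mm3", (10, 20.3, 0.6), (10, 13.8, 0.6)),
]

#: Baseline in vivo brain-compartment volumes, p73 cohort
#: (control N=8 vs knockout N=7).
P73_MORPHOMETRY: list[TableRow] = [
    _row("tiv_mm3", (8, 453.3, 6.3), (7, 362.3, 6.6)),
    _row("brain_parenchyma_mm3", (8, 442.7, 7.0), (7, 333.8, 5.2)),
    _row("cv_volume_mm3", (8, 4.4, 0.4), (7, 26.3, 2.9)),
    _row("cv_fraction_of_tiv_pct", (8, 0.98, 0.08), (7, 7.3, 0.8)),
    _row("olfactory_bulb_mm3", (8, 19.2, 0.5), (7, 7.7, 0.5)),
]

#: In-text glymphatic transport, drainage, ICP and AQP4 summaries
#: (control, mutant), each mean +/- SEM with group n.
GROUP_SUMMARIES: dict[str, tuple[GroupSummary, GroupSummary]] = dict(
    (name, (ctrl, mut)) for name, ctrl, mut in [
        _row("cep164_glymphatic_mm3", (7, 143.3, 10.0), (8, 156.2, 12.9)),
        _row("cep164_glymphatic_pct_tiv", (7, 30.0, 2.0), (8, 30.7, 3.0)),
        _row("p73_glymphatic_mm3", (8, 215.0, 12.7), (6, 218.5, 7.1)),
        _row("p73_glymphatic_pct_brain", (8, 47.6, 3.1), (6, 60.5, 2.1)),
        _row("cep164_nasal_mm3", (7, 11.3, 4.2), (8, 6.7, 2.7)),
        _row("p73_nasal_mm3", (8, 9.7, 1.1), (6, 3.3, 0.1)),
        _row("cep164_dcln_mm3", (7, 0.8, 0.1), (8, 0.75, 0.1)),
        _row("p73_dcln_mm3", (8, 1.1, 0.1), (6, 1.7, 0.1)),
        _row("p73_icp_mmhg", (4, 3.7, 1.1), (5, 2.4, 0.6)),
        _row("p73_capillary_pi", (4, 10.4, 0.7), (4, 12.9, 0.7)),
    ]
)

#: Manual-vs-automated AQP4 method agreement: printed correlation and
#: its degrees of freedom (10 paired animal means).
PEARSON_VALIDATION = {"r": 0.646, "df": 8, "p": 0.044}
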