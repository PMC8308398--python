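"""Independent literal transcriptions of the index formulas and the
status decision rules, used as oracles against the package
implementation.  Deliberately naive: no shared code with the package
beyond the raw curve container.
"""

from __future__ import annotations

import math


def oracle_panel(curve) -> dict[str, float]:
    """All five indices computed directly from their printed formulas."""
    t = list(curve.times)
    g_mgdl = [x * 18.0 for x in curve.glucose]
    ins = list(curve.insulin)
    fg_mmol = curve.glucose[0]
    fg, fi = g_mgdl[0], ins[0]
    mg = sum(g_mgdl) / len(g_mgdl)
    mi = sum(ins) / len(ins)

    matsuda = 10000.0 / math.sqrt(fg * fi * mg * mi)

    # trapezoid AUCs over [0, 30] using the first two samples
    auc_i = (ins[0] + ins[1]) / 2.0 * (t[1] - t[0])
    auc_g = (g_mgdl[0] + g_mgdl[1]) / 2.0 * (t[1] - t[0])
    disposition = auc_i / auc_g * matsuda

    hiri = fg * fi
    homa = fg_mmol * fi / 22.5

    # span-slope MISI: (Gmin - Gmax) over the positive duration between
    # the sample extrema, per mean insulin, x100
    i_max = max(range(len(g_mgdl)), key=lambda k: g_mgdl[k])
    i_min = min(range(len(g_mgdl)), key=lambda k: g_mgdl[k])
    if g_mgdl[i_max] == g_mgdl[i_min]:
        misi = 0.0
    else:
        misi = 100.0 * (g_mgdl[i_min] - g_mgdl[i_max]) / abs(t[i_min] - t[i_max]) / mi

    return {
        "matsuda": matsuda,
        "disposition": disposition,
        "hiri": hiri,
        "misi": misi,
        "homa_ir": homa,
    }


def oracle_status(hba1c: float, fpg: float, relation: str, any_meds: bool) -> str:
    """Hand transcription of the remission/reversal definitions.

    Remission: fasting glucose <= 6.9 and HbA1c < 48 and no
    glucose-lowering medication.  Reversal: HbA1c <= 53 and fasting
    glucose < 8.0 with reduced/stopped medication, or HbA1c < 48 and
    fasting glucose <= 6.9 with equal medication.  Else T2D.
    """
    if fpg <= 6.9 and hba1c < 48 and not any_meds:
        return "remission"
    if hba1c <= 53 and fpg < 8.0 and relation in ("reduced", "stopped_all"):
        return "reversal"
    if hba1c < 48 and fpg <= 6.9 and relation == "equal":
        return "reversal"
    return "T2D"
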