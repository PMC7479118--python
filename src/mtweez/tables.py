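"""Recomputation of the packaged thermal-stability reference table.

The package ships the printed measurements of the SR4 and I27 tandem-domain
experiments (force, temperature, single-domain unfolded probability p with
bootstrap SE, and the conformational term Δφ(F) with its force-calibration
error) together with the published derived quantities.  From the measured
inputs this module recomputes the full derived chain —

    ΔG(F) = −kBT ln((1−p)/p),   ΔG0 = ΔG(F) − Δφ(F),   ΔG0 + Δφ(Fc) = 0

— so the published cells can be checked against the implementation, and
additionally evaluates Δφ from the package's own WLC/rod polymer model for
comparison with the printed values.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .polymer import FoldedDomainParams, PeptideParams
from .thermo import thermo_from_measurement

__all__ = ["load_reference_table", "recompute_stability_table"]


def load_reference_table() -> list[dict]:
    """The packaged printed measurements, one dict per (domain, T) column."""
    text = resources.files("mtweez.data").joinpath("table1.json").read_text()
    return json.loads(text)["columns"]


def recompute_stability_table(use_printed_dphi: bool = True) -> pd.DataFrame:
    """Recompute ΔG(F), ΔG0 and Fc for every reference column.

    With ``use_printed_dphi`` the printed Δφ(F) enters the ΔG0 arithmetic
    (the published convention); otherwise Δφ is taken from the package's
    polymer model.  Fc is always solved through the polymer model.  The
    returned frame holds measured inputs, recomputed values, the printed
    values, and a model-quadrature Δφ column ``dPhi_model``.
    """
    rows = []
    for col in load_reference_table():
        unfolded = PeptideParams(n_residues=col["n_residues"])
        folded = FoldedDomainParams(rod_length=col["rod_length_nm"])
        res = thermo_from_measurement(
            force=col["force"], temperature=col["temperature"],
            p=col["p"], p_se=col["p_se"],
            unfolded=unfolded, folded=folded,
            dPhi_F=col["dPhi"] if use_printed_dphi else None,
            dPhi_F_se=col["dPhi_se"] if use_printed_dphi else None,
        )
        model_only = thermo_from_measurement(
            force=col["force"], temperature=col["temperature"],
            p=col["p"], p_se=col["p_se"],
            unfolded=unfolded, folded=folded,
        )
        rows.append({
            "domain": col["domain"],
            "temperature": col["temperature"],
            "force": col["force"],
            "p": col["p"],
            "dPhi": res.dPhi_F,
            "dPhi_model": model_only.dPhi_F,
            "dPhi_model_se": model_only.dPhi_F_se,
            "dG": res.dG_F,
            "dG_se": res.dG_F_se,
            "dG_printed": col["dG_printed"],
            "dG0": res.dG0,
            "dG0_se": res.dG0_se,
            "dG0_printed": col["dG0_printed"],
            "Fc": res.Fc,
            "Fc_se": res.Fc_se,
            "Fc_printed": col["Fc_printed"],
        })
    return pd.DataFrame(rows)
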