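"""Serialization of fits and gridded arrays (CSV / JSON)."""

from __future__ import annotations

import hashlib
import json

import numpy as np
import pandas as pd

from .basis import TensorSmoothSpec
from .binning import BinnedCompRisks, TwoTimeGrid
from .fit import CauseFit


def grid_to_dict(grid: TwoTimeGrid) -> dict:
    return {"u_min": grid.u_min, "u_max": grid.u_max,
            "s_min": grid.s_min, "s_max": grid.s_max,
            "h_u": grid.h_u, "h_s": grid.h_s,
            "n_u": grid.n_u, "n_s": grid.n_s}


def grid_from_dict(d: dict) -> TwoTimeGrid:
    return TwoTimeGrid(**d)


def write_binned(binned: BinnedCompRisks, prefix) -> None:
    """Write long-format CSV plus three rectangular matrices."""
    binned.to_long_frame().to_csv(f"{prefix}_long.csv", index=False)
    for name, arr in (("r", binned.R), ("y1", binned.Y[0]),
                      ("y2", binned.Y[1])):
        pd.DataFrame(arr, index=binned.grid.u_mid,
                     columns=binned.grid.s_mid).to_csv(f"{prefix}_{name}.csv")


def read_binned(prefix, grid: TwoTimeGrid) -> BinnedCompRisks:
    arrs = {}
    for name in ("r", "y1", "y2"):
        arrs[name] = pd.read_csv(f"{prefix}_{name}.csv", index_col=0).to_numpy()
    return BinnedCompRisks(grid=grid, R=arrs["r"],
                           Y=[arrs["y1"], arrs["y2"]])


def fit_to_dict(fit: CauseFit, spec_config: dict | None = None) -> dict:
    return {
        "cause": fit.cause,
        "A_hat": fit.A_hat.tolist(),
        "rho_u": fit.rho_u, "rho_s": fit.rho_s,
        "deviance": fit.deviance, "ed": fit.ed,
        "aic": fit.aic, "bic": fit.bic, "n_bin": fit.n_bin,
        "converged": bool(fit.converged), "n_iter": fit.n_iter,
        "spec": spec_config or {},
    }


def fit_from_dict(d: dict, spec: TensorSmoothSpec, R: np.ndarray) -> CauseFit:
    from .glam import glam_eta
    A = np.asarray(d["A_hat"], dtype=float)
    eta = glam_eta(spec.basis_u.B, spec.basis_s.B, A)
    mu = np.where(R > 0, R * np.exp(eta), 0.0)
    return CauseFit(cause=d["cause"], A_hat=A, rho_u=d["rho_u"],
                    rho_s=d["rho_s"], eta_hat=eta, mu_hat=mu,
                    deviance=d["deviance"], ed=d["ed"], aic=d["aic"],
                    bic=d["bic"], n_bin=d["n_bin"],
                    converged=d["converged"], n_iter=d["n_iter"], spec=spec)


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def surfaces_to_frame(surfaces) -> pd.DataFrame:
    """Long-format (u, s, Lambda1, Lambda2, S, I1, I2)."""
    rows = []
    for i, u in enumerate(surfaces.u_values):
        for j, s in enumerate(surfaces.s_values):
            rows.append({
                "u": u, "s": s,
                "Lambda1": surfaces.Lambda[0, i, j],
                "Lambda2": surfaces.Lambda[1, i, j],
                "S": surfaces.S[i, j],
                "I1": surfaces.I[0, i, j],
                "I2": surfaces.I[1, i, j],
            })
    return pd.DataFrame(rows)


def summary_table(surfaces, at, ci=None) -> pd.DataFrame:
    """Tabular summary of S and the CIFs at requested (u, s) pairs.

    With a bootstrap result attached, each row gains lo/hi columns for the
    two CIFs (normal-based interval at the bootstrap's level).
    """
    rows = []
    for (u, s) in at:
        S, I1, I2 = surfaces.at(u, s)
        row = {"u": u, "s": s, "S": S, "I1": I1, "I2": I2}
        if ci is not None:
            iu = int(np.argmin(np.abs(ci.u_values - u)))
            js = int(np.argmin(np.abs(ci.s_values - s)))
            if (abs(ci.u_values[iu] - u) > 1e-9
                    or abs(ci.s_values[js] - s) > ci.s_values[1] / 2):
                raise ValueError(f"({u}, {s}) not on the bootstrap grid")
            for ell, name in ((0, "I1"), (1, "I2")):
                row[f"{name}_lo"] = float(ci.ci_lo[ell, iu, js])
                row[f"{name}_hi"] = float(ci.ci_hi[ell, iu, js])
        rows.append(row)
    return pd.DataFrame(rows)
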