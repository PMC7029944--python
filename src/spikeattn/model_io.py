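"""JSON (de)serialization of fitted models."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .cbm import CBMParams
from .hmm import HMMParams
from .point_process import CIFParams

__all__ = ["model_to_dict", "model_from_dict", "write_model", "read_model"]


def model_to_dict(params: HMMParams | CBMParams, meta: dict | None = None) -> dict:
    doc: dict = {"meta": meta or {}}
    if isinstance(params, HMMParams):
        doc.update({
            "model": "hmm",
            "lambda": params.lam.tolist(),
            "Gamma": {str(m): g.tolist() for m, g in params.Gamma.items()},
            "alpha": params.alpha.tolist(),
        })
    elif isinstance(params, CBMParams):
        doc.update({
            "model": "cbm",
            "p1": params.p1,
            "rho1": params.rho1,
            "p": {str(m): {str(t): v for t, v in tbl.items()}
                  for m, tbl in params.p.items()},
            "rho": {str(m): {str(t): v for t, v in tbl.items()}
                    for m, tbl in params.rho.items()},
            "n_intervals": params.n_intervals,
        })
    else:
        raise TypeError(f"cannot serialize {type(params).__name__}")
    doc["rates"] = {nid: dict(tbl) for nid, tbl in params.cif.rates.items()}
    doc["beta"] = params.cif.beta.tolist()
    return doc


def model_from_dict(doc: dict) -> HMMParams | CBMParams:
    cif = CIFParams(rates={nid: dict(tbl) for nid, tbl in doc["rates"].items()},
                    beta=np.asarray(doc["beta"], dtype=float))
    if doc["model"] == "hmm":
        return HMMParams(
            lam=np.asarray(doc["lambda"], dtype=float),
            Gamma={int(m): np.asarray(g, dtype=float)
                   for m, g in doc["Gamma"].items()},
            alpha=np.asarray(doc["alpha"], dtype=float),
            cif=cif,
        )
    if doc["model"] == "cbm":
        return CBMParams(
            p1=float(doc["p1"]), rho1=float(doc["rho1"]),
            p={int(m): {int(t): float(v) for t, v in tbl.items()}
               for m, tbl in doc["p"].items()},
            rho={int(m): {int(t): float(v) for t, v in tbl.items()}
                 for m, tbl in doc["rho"].items()},
            cif=cif, n_intervals=int(doc["n_intervals"]),
        )
    raise ValueError(f"unknown model kind {doc.get('model')!r}")


def write_model(params, path, meta: dict | None = None) -> None:
    Path(path).write_text(json.dumps(model_to_dict(params, meta), indent=1))


def read_model(path):
    return model_from_dict(json.loads(Path(path).read_text()))
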