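"""Containers and configuration.

Trial sets and models are stored in hierarchical HDF5 files (one file per
object); CSV is supported for importing long-format tables of user data.
Run configuration is YAML with strict key validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
import yaml

from .basis import (BasisSet, ConditionDomain, DomainDimension,
                    FunctionWeights, build_basis, project_function)
from .model import CLDSModel, ParamFunction, Trial, TrialSet

__all__ = ["read_trialset", "write_trialset", "read_trialset_csv",
           "read_model", "write_model", "RunConfig", "read_config"]

FORMAT_VERSION = 1


# -- domain (de)serialization -------------------------------------------------


def _domain_to_json(domain: ConditionDomain) -> str:
    return json.dumps([
        {"kind": d.kind, "lower": d.lower, "upper": d.upper,
         "lengthscale": d.lengthscale, "variance": d.variance,
         "levels": list(d.levels)}
        for d in domain.dims
    ])


def _domain_from_json(text: str) -> ConditionDomain:
    dims = []
    for d in json.loads(text):
        dims.append(DomainDimension(
            kind=d["kind"], lower=d["lower"], upper=d["upper"],
            lengthscale=d["lengthscale"], variance=d["variance"],
            levels=tuple(d["levels"])))
    return ConditionDomain(tuple(dims))


# -- trial sets ---------------------------------------------------------------


def write_trialset(trialset: TrialSet, path):
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["domain"] = _domain_to_json(trialset.domain)
        f.attrs["metadata"] = json.dumps(trialset.metadata)
        grp = f.create_group("trials")
        for k, tr in enumerate(trialset):
            g = grp.create_group(str(k))
            g.create_dataset("y", data=tr.y)
            g.create_dataset("u", data=tr.u)
            if tr.x is not None:
                g.create_dataset("x", data=tr.x)


def read_trialset(path) -> TrialSet:
    with h5py.File(path, "r") as f:
        if "trials" not in f or "domain" not in f.attrs:
            raise ValueError(f"{path} is not a trial-set container")
        domain = _domain_from_json(f.attrs["domain"])
        metadata = json.loads(f.attrs.get("metadata", "{}"))
        keys = sorted(f["trials"].keys(), key=int)
        trials = []
        for k in keys:
            g = f["trials"][k]
            x = g["x"][()] if "x" in g else None
            trials.append(Trial(y=g["y"][()], u=g["u"][()], x=x))
    return TrialSet(trials=trials, domain=domain, metadata=metadata)


def read_trialset_csv(path, domain: ConditionDomain) -> TrialSet:
    """Import a long-format CSV with columns ``trial``, ``t``, neuron columns
    ``y0..y{N-1}`` and covariate columns ``u0..u{d-1}``."""
    df = pd.read_csv(path)
    required = {"trial", "t"}
    if not required.issubset(df.columns):
        raise ValueError("CSV must contain 'trial' and 't' columns")
    ycols = sorted([c for c in df.columns if c.startswith("y")],
                   key=lambda c: int(c[1:]))
    ucols = sorted([c for c in df.columns if c.startswith("u")],
                   key=lambda c: int(c[1:]))
    if not ycols or not ucols:
        raise ValueError("CSV must contain y<i> and u<j> columns")
    trials = []
    for _, block in df.groupby("trial", sort=True):
        block = block.sort_values("t")
        trials.append(Trial(y=block[ycols].to_numpy(float),
                            u=block[ucols].to_numpy(float)))
    return TrialSet(trials=trials, domain=domain)


# -- models -------------------------------------------------------------------

_SHAPES = {"A": lambda D, N: (D, D), "b": lambda D, N: (D,),
           "C": lambda D, N: (N, D), "d": lambda D, N: (N,),
           "m": lambda D, N: (D,)}


def default_projection_grid(domain: ConditionDomain, n_per_dim: int = 96):
    """Dense covariate grid used to project analytic parameter functions
    for serialization (Cartesian product across dimensions)."""
    axes = []
    for d in domain.dims:
        if d.kind == "discrete_embedded":
            axes.append(np.asarray(d.levels, dtype=float))
        elif d.kind == "periodic":
            axes.append(np.linspace(d.lower, d.upper, n_per_dim,
                                    endpoint=False))
        else:
            axes.append(np.linspace(d.lower, d.upper, n_per_dim))
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=1)


def write_model(model: CLDSModel, path, basis: BasisSet | None = None,
                projection_grid=None):
    """Serialize a model.  Analytic (callable) parameter functions are
    projected onto ``basis`` (or ``model.basis``) over ``projection_grid``
    (a domain-covering default if omitted) and marked as projected;
    weight-based functions round-trip bitwise."""
    basis = basis or model.basis
    if projection_grid is None and model.domain is not None:
        projection_grid = default_projection_grid(model.domain)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["D"] = model.D
        f.attrs["N"] = model.N
        f.attrs["fixed"] = json.dumps(sorted(model.fixed))
        f.attrs["domain"] = _domain_to_json(model.domain)
        if basis is None:
            raise ValueError("serializing a model requires a basis")
        # the basis the stored weights refer to (may differ from the model's
        # domain hyperparameters, e.g. a finer projection basis)
        f.attrs["basis_domain"] = _domain_to_json(basis.domain)
        f.attrs["L_per_dim"] = json.dumps(list(basis.L_per_dim))
        for name in ("Q1", "Q", "R"):
            f.create_dataset(name, data=getattr(model, name))
        for name in ("A", "b", "C", "d", "m"):
            pf: ParamFunction = getattr(model, name)
            g = f.create_group(f"functions/{name}")
            if pf.is_parametric:
                g.attrs["projected"] = False
                g.create_dataset("W", data=pf.weights.W)
                g.attrs["D1"] = pf.weights.D1
                g.attrs["D2"] = pf.weights.D2
            else:
                if projection_grid is None:
                    raise ValueError(
                        "model has analytic functions; provide projection_grid")
                shape = pf.shape
                D1 = shape[0]
                D2 = shape[1] if len(shape) > 1 else 1
                fw = project_function(
                    lambda u, _pf=pf: _pf(basis, u).reshape(D1, D2),
                    basis, D1, D2, projection_grid, label=name)
                g.attrs["projected"] = True
                g.create_dataset("W", data=fw.W)
                g.attrs["D1"] = D1
                g.attrs["D2"] = D2


def read_model(path) -> CLDSModel:
    with h5py.File(path, "r") as f:
        if "functions" not in f:
            raise ValueError(f"{path} is not a model container")
        version = int(f.attrs.get("format_version", -1))
        if version != FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {version}")
        D = int(f.attrs["D"])
        N = int(f.attrs["N"])
        fixed = frozenset(json.loads(f.attrs["fixed"]))
        domain = _domain_from_json(f.attrs["domain"])
        basis_domain = _domain_from_json(f.attrs["basis_domain"])
        L_per_dim = tuple(json.loads(f.attrs["L_per_dim"]))
        basis = build_basis(basis_domain, L_per_dim)
        covs = {name: f[name][()] for name in ("Q1", "Q", "R")}
        funcs = {}
        for name in ("A", "b", "C", "d", "m"):
            g = f["functions"][name]
            fw = FunctionWeights(D1=int(g.attrs["D1"]), D2=int(g.attrs["D2"]),
                                 W=g["W"][()], label=name)
            funcs[name] = ParamFunction(_SHAPES[name](D, N), weights=fw,
                                        name=name)
    return CLDSModel(D=D, N=N, **funcs, **covs, basis=basis, domain=domain,
                     fixed=fixed)


# -- run configuration --------------------------------------------------------

_SCHEMA = {
    "model": {"n_latents", "n_basis", "fix_C_to_truth", "learn_d",
              "learn_Q1", "basis"},
    "em": {"max_iter", "tol", "seed"},
    "data": {"path", "simulate"},
    "eval": {"top_k", "test_fraction", "split_seed"},
}
_SIM_KEYS = {"epsilon", "n_neurons", "T", "K", "heading_step_sd",
             "obs_noise_sd", "dyn_noise_sd", "bump_sharpness", "seed",
             "lengthscale", "variance"}
_BASIS_KEYS = {"kind", "lower", "upper", "lengthscale", "variance", "levels"}


@dataclass
class RunConfig:
    """Validated run configuration (see README for the YAML schema)."""

    model: dict = field(default_factory=dict)
    em: dict = field(default_factory=dict)
    data: dict = field(default_factory=dict)
    eval: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - set(_SCHEMA)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        for section, keys in _SCHEMA.items():
            bad = set(raw.get(section, {})) - keys
            if bad:
                raise ValueError(
                    f"unknown keys in [{section}]: {sorted(bad)}")
        sim = raw.get("data", {}).get("simulate") or {}
        bad = set(sim) - _SIM_KEYS
        if bad:
            raise ValueError(f"unknown keys in [data.simulate]: {sorted(bad)}")
        for b in raw.get("model", {}).get("basis") or []:
            bad = set(b) - _BASIS_KEYS
            if bad:
                raise ValueError(f"unknown keys in basis dim: {sorted(bad)}")
        return cls(model=dict(raw.get("model", {})),
                   em=dict(raw.get("em", {})),
                   data=dict(raw.get("data", {})),
                   eval=dict(raw.get("eval", {})))

    def to_dict(self) -> dict:
        return {"model": self.model, "em": self.em, "data": self.data,
                "eval": self.eval}

    def domain(self) -> ConditionDomain | None:
        dims = self.model.get("basis")
        if not dims:
            return None
        return ConditionDomain(tuple(
            DomainDimension(
                kind=d["kind"], lower=float(d["lower"]),
                upper=float(d["upper"]),
                lengthscale=float(d["lengthscale"]),
                variance=float(d.get("variance", 1.0)),
                levels=tuple(d.get("levels", ())))
            for d in dims))


def read_config(path) -> RunConfig:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    return RunConfig.from_dict(raw)
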