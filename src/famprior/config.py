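"""Pipeline configuration: defaults and YAML overrides.

The defaults encode the published filter settings: call-quality minima of 20
(homozygous) and 40 (heterozygous), a 1% MAF ceiling across three reference
databases, deleteriousness cutoffs SIFT < 0.05 / PolyPhen > 0.85 / GERP++ > 2,
and the CNV post-filters (>= 10 markers, mean inter-marker gap <= 50 kb, > 50%
blacklist overlap removal).
"""

from __future__ import annotations

import copy
from typing import Any, Dict, Optional

import yaml

__all__ = ["DEFAULTS", "load_config", "get"]

DEFAULTS: Dict[str, Any] = {
    "quality": {"hom_min": 20.0, "het_min": 40.0},
    "maf": {"threshold": 0.01, "databases": ["thousand_genomes", "esp5400", "cg46"]},
    "scores": {
        "sift_max": 0.05,
        "polyphen_min": 0.85,  # 0.80 is the looser published reading
        "gerp_min": 2.0,
        "missing_passes": True,
    },
    "genes": {"splice_window": 2, "flank_bp": 1000},
    "noncoding": {
        "conserved_score_min": 2.0,
        # chromHMM 15-state model of the GM12878 lymphoblastoid line
        "chromatin_keep": {1: "active promoter", 4: "strong enhancer", 5: "strong enhancer"},
    },
    "cnv": {
        "min_snps": 10,
        "max_mean_gap": 50000.0,
        "blacklist_max_frac": 0.5,
        "erds": {"del_min_bp": 10000, "dup_min_bp": 200000, "conf_min": 300.0},
        "reciprocal_min": 0.5,
        "evidence": {
            "depth_max": 0.75,
            "het_band": [0.25, 0.75],
            "het_frac_max": 0.1,
        },
    },
    "ibd": {"include_x": False},
}


def _merge(base: Dict[str, Any], override: Dict[str, Any]) -> Dict[str, Any]:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _expand_dotted(d: Dict[str, Any]) -> Dict[str, Any]:
    """Allow flat keys like ``maf.threshold: 0.02`` in YAML overrides."""
    out: Dict[str, Any] = {}
    for k, v in d.items():
        if isinstance(k, str) and "." in k:
            head, rest = k.split(".", 1)
            out.setdefault(head, {})
            sub = _expand_dotted({rest: v})
            out[head] = _merge(out[head], sub) if isinstance(out[head], dict) else sub
        elif isinstance(v, dict):
            out[k] = _merge(out.get(k, {}), _expand_dotted(v)) if isinstance(out.get(k), dict) else _expand_dotted(v)
        else:
            out[k] = v
    return out


def load_config(path: Optional[str] = None) -> Dict[str, Any]:
    """Defaults, deep-merged with an optional YAML override file."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            override = yaml.safe_load(fh) or {}
        if not isinstance(override, dict):
            raise ValueError(f"{path}: config must be a mapping")
        cfg = _merge(cfg, _expand_dotted(override))
    return cfg


def get(cfg: Dict[str, Any], dotted: str) -> Any:
    """Fetch ``cfg`` values by dotted path, e.g. ``get(cfg, "maf.threshold")``."""
    cur: Any = cfg
    for part in dotted.split("."):
        cur = cur[part]
    return cur
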