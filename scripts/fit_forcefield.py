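"""Regenerate the versioned default force-field parameter file.

Measures every equilibrium geometry value from the ideal-helix fixture
(deterministic) and writes src/circfold/data/forcefield_v1.yaml.

Run:  python scripts/fit_forcefield.py
"""
import pathlib

import yaml

from circfold.forcefield import fit_default_params, params_to_dict

out = pathlib.Path(__file__).resolve().parents[1] / "src" / "circfold" / "data" / "forcefold_tmp"
out = out.with_name("forcefield_v1.yaml")
params = fit_default_params()
out.write_text(yaml.safe_dump(params_to_dict(params), sort_keys=True))
print(f"wrote {out}")
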