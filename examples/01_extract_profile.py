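"""Extract bridge parameters from a proton-transfer scan profile.

Builds a 21-point double-well curve (the shape a relaxed O–H scan of an
intramolecular O–H...N bridge produces), writes it to a CSV, reads it
back and extracts the activation energy (EA), the second minimum (SM)
and their difference.
"""

import tempfile
from pathlib import Path

from ptbridge import (
    extract_bridge_parameters,
    generate_profile,
    read_profile,
    write_profile,
)

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "scan.csv"
    write_profile(generate_profile(ea=12.0, sm=10.0), path)

    profile = read_profile(path)  # energies re-zeroed on the first point
    params = extract_bridge_parameters(profile)

print(f"scan points          : {profile.n_points} (step {profile.step:.2f} Å)")
print(f"activation energy EA : {params.activation_energy:.3f} kcal/mol")
print(f"second minimum SM    : {params.second_minimum:.3f} kcal/mol")
print(f"difference EA - SM   : {params.difference:.3f} kcal/mol")
# EA is the barrier the bridged proton must cross to reach the nitrogen
# acceptor; SM is the relative energy of the proton-transferred form. A
# small difference means a flat, easily reversible proton-transfer well.
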