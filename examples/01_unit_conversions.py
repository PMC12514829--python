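"""Dissolved-oxygen unit conversions through the air-saturation anchors.

Oxygen levels in respirometry are quoted interchangeably as % air
saturation, µmol O₂/L and kPa.  Conversions are linear once the water's
100%-saturation anchors are fixed — either computed from temperature /
salinity / pressure via the seawater solubility model, or supplied
directly to reproduce published equivalences exactly.
"""

from oxyscope import (
    KPA,
    PERCENT_AIRSAT,
    UMOL_PER_L,
    WaterConditions,
    convert_o2,
    saturation_concentration,
)

# Physical anchors from the solubility model at 2 °C, S 34
model = WaterConditions(temperature=2.0, salinity=34.0)
print(f"solubility model at 2 °C, S 34: "
      f"{saturation_concentration(model):.2f} µmol O₂/L, "
      f"sat PO₂ {model.sat_po2:.3f} kPa")

# Anchors pinned to a published conversion table
anchored = WaterConditions(
    temperature=2.0, salinity=34.0, sat_concentration=366.67, sat_po2=20.857
)
print(f"75% air sat  = {convert_o2(75, PERCENT_AIRSAT, UMOL_PER_L, anchored):.2f} µmol O₂/L")
print(f" 7% air sat  = {convert_o2(7, PERCENT_AIRSAT, KPA, anchored):.2f} kPa")
print(f"45 µmol O₂/L = {convert_o2(45, UMOL_PER_L, PERCENT_AIRSAT, anchored):.2f} % air sat")
# The first line reproduces the deep-basin oxygen level of the study site;
# the second is the magnitude of a typical optode calibration offset.
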