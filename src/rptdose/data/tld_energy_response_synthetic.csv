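# Synthetic TLD-100 relative energy-response curve (response per unit dose,
# normalized to the Cs-137 reference quality at 662 keV). These anchor values
# are a plausible stand-in bounded by the ~40% low-energy over-response
# reported for LiF:Mg,Ti; they are NOT measured data and are overridable.
energy_keV,relative_response
30,1.40
60,1.32
111,1.18
200,1.10
300,1.06
400,1.03
662,1.00
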