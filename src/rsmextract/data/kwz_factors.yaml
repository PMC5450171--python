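# Extraction factors for the KWZ (Kursi Wufarikun Ziyabit) two-plant
# prescription study: low/center/high natural levels mapping to coded
# -1/0/+1.  The solid-to-solvent ratio "1 : N g/mL" is stored as the
# scalar N.
factors:
  - name: ethanol
    unit: "%"
    low: 30
    center: 50
    high: 70
  - name: temperature
    unit: "degC"
    low: 60
    center: 70
    high: 80
  - name: ratio
    unit: "mL/g"
    low: 10
    center: 20
    high: 30
  - name: time
    unit: "h"
    low: 2
    center: 3
    high: 4
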