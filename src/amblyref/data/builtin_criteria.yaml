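- name: aapos_2021
  display_name: AAPOS 2021
  bands:
    under4:
      hyperopia_ge: 4.0
      myopia_le: -3.0
      astigmatism_ge: 3.0
      anisometropia_ge: 1.25
    ge4:
      hyperopia_ge: 4.0
      myopia_le: -2.0
      astigmatism_ge: 1.75
      anisometropia_ge: 1.25
- name: arthur
  display_name: Arthur
  bands:
    under4:
      hyperopia_ge: 3.5
      myopia_le: -3.0
      astigmatism_ge: 1.25
      anisometropia_ge: 1.0
    ge4:
      hyperopia_ge: 3.5
      myopia_le: -3.0
      astigmatism_ge: 1.25
      anisometropia_ge: 1.0
- name: arnold_medium
  display_name: Arnold Medium
  bands:
    under4:
      hyperopia_ge: 3.0
      myopia_le: -3.5
      astigmatism_ge: 3.5
      anisometropia_ge: 1.75
    ge4:
      hyperopia_ge: 3.0
      myopia_le: -2.5
      astigmatism_ge: 2.5
      anisometropia_ge: 1.75
- name: arnold_specific
  display_name: Arnold Specific
  bands:
    under4:
      hyperopia_ge: 3.5
      myopia_le: -3.5
      astigmatism_ge: 3.75
      anisometropia_ge: 1.75
    ge4:
      hyperopia_ge: 3.5
      myopia_le: -2.5
      astigmatism_ge: 2.75
      anisometropia_ge: 1.75
- name: matta_silbert
  display_name: Matta & Silbert
  bands:
    under4:
      hyperopia_ge: 1.25
      myopia_le: -1.0
      astigmatism_ge: 1.0
      anisometropia_ge: 1.25
    ge4:
      hyperopia_ge: 1.25
      myopia_le: -1.0
      astigmatism_ge: 1.0
      anisometropia_ge: 1.25
- name: abcd
  display_name: Alaska Blind Child Discovery
  bands:
    under4:
      hyperopia_ge: 2.5
      myopia_le: -2.25
      astigmatism_ge: 2.25
      anisometropia_ge: 1.0
    ge4:
      hyperopia_ge: 2.5
      myopia_le: -2.25
      astigmatism_ge: 2.25
      anisometropia_ge: 1.0
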