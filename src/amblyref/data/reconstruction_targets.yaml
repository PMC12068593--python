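# Published count table of the screening study (308 children, 616 eyes):
# per-criterion category counts and overall referral counts, device code
# counts, and the demographic margins used to materialize the fixture cohort.
cohort_size: 308
band_sizes:
  under4: 106
  ge4: 202
codes:
  hyp: 7
  myo: 1
  unreadable: 2
reference_criterion: aapos_2021
category_counts:
  aapos_2021: {hyperopia: 7, myopia: 14, astigmatism: 37, anisometropia: 14}
  arthur: {hyperopia: 10, myopia: 5, astigmatism: 69, anisometropia: 17}
  arnold_medium: {hyperopia: 11, myopia: 4, astigmatism: 20, anisometropia: 5}
  arnold_specific: {hyperopia: 10, myopia: 4, astigmatism: 14, anisometropia: 5}
  matta_silbert: {hyperopia: 38, myopia: 26, astigmatism: 93, anisometropia: 14}
  abcd: {hyperopia: 11, myopia: 10, astigmatism: 30, anisometropia: 17}
union_counts:
  aapos_2021: 69
  arthur: 87
  arnold_medium: 35
  arnold_specific: 28
  matta_silbert: 129
  abcd: 55
schools:
  sizes: {public: 114, private: 194}
  band_sizes:
    public: {under4: 13, ge4: 101}
    private: {under4: 93, ge4: 101}
  referred: {public: 41, private: 28}
  glasses_referred: {public: 2, private: 26}
  referred_public_categories: {hyperopia: 5, myopia: 8, astigmatism: 25, anisometropia: 1}
  females: {public: 52, private: 94}
  grades:
    public:
      under4: [[kg1, 13]]
      ge4: [[kg2, 22], [kg3, 40], [grade1, 39]]
    private:
      under4: [[nursery, 46], [kg1, 47]]
      ge4: [[kg2, 74], [kg3, 27]]
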