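{
  "version": "episig-table-v1",
  "comment": "Clinical features of the 32-case Clark-Baraitser (TRIP12) cohort. Each feature maps to the case ids reported positive; dysmorphic features, speech delay and global developmental delay were present in all individuals, intellectual disability in all but case 22, motor delay in all but cases 9, 26 and 27.",
  "features": {
    "dysmorphic_features": [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20, 21, 22, 23, 24, 25, 26, 27, 28, 29, 30, 31, 32],
    "speech_delay": [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20, 21, 22, 23, 24, 25, 26, 27, 28, 29, 30, 31, 32],
    "global_developmental_delay": [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20, 21, 22, 23, 24, 25, 26, 27, 28, 29, 30, 31, 32],
    "intellectual_disability": [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20, 21, 23, 24, 25, 26, 27, 28, 29, 30, 31, 32],
    "motor_delay": [1, 2, 3, 4, 5, 6, 7, 8, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20, 21, 22, 23, 24, 25, 28, 29, 30, 31, 32],
    "obesity": [1, 2, 6, 7, 8, 12, 14, 15, 21, 23, 26, 30, 32]
  },
  "previously_described_ids": [1, 2, 3, 5, 6, 7, 8, 9, 12, 13, 14, 15, 16, 17, 18, 19, 20, 21, 23, 24, 26, 27, 28, 29, 30, 31, 32],
  "previously_described_stated_count": 28
}
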