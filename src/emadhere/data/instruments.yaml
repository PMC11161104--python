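# Item-to-scale maps for the questionnaire instruments.
#
# The beliefs-about-medicines questionnaire (BMQ) has 18 items on a 1-5
# Likert scale (1 = strongly agree ... 5 = strongly disagree); every item is
# reverse-scored (6 - raw) and subscales are sums of reversed items, so
# higher scores mean stronger beliefs.  Verify the reverse-scoring direction
# of each item against the instrument manual before scoring real data.
#
# The 30-item cancer quality-of-life core questionnaire (QLQ-C30) is scored
# here as its three summary domains: functioning (15 items, 1-4), symptoms
# (13 items, 1-4) and global health status (2 items, 1-7), each linearly
# transformed to 0-100 from the mean raw item score.
bmq:
  necessity: [bmq_nec1, bmq_nec2, bmq_nec3, bmq_nec4, bmq_nec5]
  concerns: [bmq_con1, bmq_con2, bmq_con3, bmq_con4, bmq_con5]
  overprescribing: [bmq_over1, bmq_over2, bmq_over3, bmq_over4]
  prejudices: [bmq_prej1, bmq_prej2, bmq_prej3, bmq_prej4]
qlq:
  functional: [q01, q02, q03, q04, q05, q06, q07, q20, q21, q22, q23, q24, q25, q26, q27]
  symptom: [q08, q09, q10, q11, q12, q13, q14, q15, q16, q17, q18, q19, q28]
  global: [q29, q30]
qlq_item_range:
  default: [1, 4]
  q29: [1, 7]
  q30: [1, 7]
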