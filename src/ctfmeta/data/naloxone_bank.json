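{
 "items": [
  {"id": "q1", "statement": "Naloxone coprescription efforts have been shown to increase access to naloxone for high-risk patients only in primary care settings.", "answer": "F"},
  {"id": "q2", "statement": "Higher doses of naloxone may be safely used if a person is suspected of overdosing from synthetic opioids such as Fentanyl.", "answer": "T"},
  {"id": "q3", "statement": "Clinicians can prescribe only naloxone to patients receiving opioid prescriptions.", "answer": "F"},
  {"id": "q4", "statement": "A person under the influence of an opioid can be arrested and charged for being under the influence of a controlled substance if he or she seeks medical assistance for himself or herself or someone else.", "answer": "F"},
  {"id": "q5", "statement": "The cheapest form of naloxone is the naloxone autoinjector made by Evzio.", "answer": "F"},
  {"id": "q6", "statement": "Writing a prescription for Evzio, Narcan, or generic will each result in a patient receiving the same product.", "answer": "F"},
  {"id": "q7", "statement": "Naloxone should be coprescribed to patients only with a RIOSORD score of >18.", "answer": "F", "group": "riosord"},
  {"id": "q8", "statement": "Facilitators involved in leading the implementation of a naloxone coprescribing program are limited to clinical staff.", "answer": "F"},
  {"id": "q9", "statement": "Academic detailing is a service provided by academic professionals (ie, faculty at educational institutions) who provide clinicians with information on new clinical guidelines and how to implement them.", "answer": "T"},
  {"id": "q10", "statement": "A social marketing program for patients is likely to be more effective in a larger health system such as JerseyCare, as opposed to a smaller practice such as Johnson Family Practice.", "answer": "F"},
  {"id": "q11", "statement": "Tailoring aspects of the naloxone coprescription checklist to accommodate your practice is not recommended because it will limit the effectiveness of the naloxone coprescription program.", "answer": "F"},
  {"id": "q12", "statement": "The RIOSORD tool calculates a patient's risk of overdose according to his or her mental health comorbidities.", "answer": "F", "group": "riosord"},
  {"id": "q13", "statement": "Developing a stakeholder analysis can be an effective way to both engage and motivate stakeholders as well as facilitate buy-in to your coprescribing program.", "answer": "T"},
  {"id": "q14", "statement": "Organizational Readiness Assessments allow facilitators to identify the likelihood that instituting a change in their practice will be successful.", "answer": "T"},
  {"id": "q15", "statement": "Gap analyses reveal unmet gaps in naloxone coprescribing to patients with a RIOSORD score of >18.", "answer": "F", "group": "riosord"},
  {"id": "q16", "statement": "Studies show that patients prescribed naloxone are more likely to engage in risky opioid-related behaviors because of a decreased perception of risk.", "answer": "F"},
  {"id": "q17", "statement": "Provider stigma is a barrier to coprescribing naloxone.", "answer": "T"},
  {"id": "q18", "statement": "The RE-AIM framework is useful in structuring the evaluation and sustainability of your naloxone coprescription program.", "answer": "T"},
  {"id": "q19", "statement": "Providers in private practice with <10 staff members can implement the RE-AIM framework and naloxone coprescribing checklist effectively.", "answer": "T"},
  {"id": "q20", "statement": "In order to have the best results, implementation frameworks must be used in full and should not be combined.", "answer": "F"}
 ]
}
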