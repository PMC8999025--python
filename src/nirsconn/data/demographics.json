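{
  "comment": "Marital-status and education head counts of the 54-worker cohort (overall and the three shift groups).",
  "groups": ["total", "morning", "afternoon", "night"],
  "n": [54, 17, 18, 19],
  "categories": {
    "Marital status": {
      "Married": [48, 16, 17, 15],
      "Unmarried": [6, 1, 1, 4]
    },
    "Education information": {
      "Bachelor's degree": [4, 1, 2, 1],
      "College": [12, 5, 3, 4],
      "High school": [27, 5, 11, 11],
      "Junior high school": [1, 1, 0, 0],
      "Technical secondary school": [10, 5, 2, 3]
    }
  }
}
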