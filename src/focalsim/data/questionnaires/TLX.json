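{
  "abbreviation": "TLX",
  "items": [
    {
      "id": "mental_demand",
      "prompt": "How mentally demanding was the task?",
      "scale": {"min": 0, "max": 100, "labels": ["Very Low", "Very High"]}
    },
    {
      "id": "physical_demand",
      "prompt": "How physically demanding was the task?",
      "scale": {"min": 0, "max": 100, "labels": ["Very Low", "Very High"]}
    },
    {
      "id": "temporal_demand",
      "prompt": "How hurried or rushed was the pace of the task?",
      "scale": {"min": 0, "max": 100, "labels": ["Very Low", "Very High"]}
    },
    {
      "id": "performance",
      "prompt": "How successful were you in accomplishing what you were asked to do?",
      "scale": {"min": 0, "max": 100, "labels": ["Perfect", "Failure"]}
    },
    {
      "id": "effort",
      "prompt": "How hard did you have to work to accomplish your level of performance?",
      "scale": {"min": 0, "max": 100, "labels": ["Very Low", "Very High"]}
    },
    {
      "id": "frustration",
      "prompt": "How insecure, discouraged, irritated, stressed, and annoyed were you?",
      "scale": {"min": 0, "max": 100, "labels": ["Very Low", "Very High"]}
    }
  ]
}
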