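{
  "root_collection": "C2",
  "tabs": [
    {
      "collection": "C2",
      "components": [
        {
          "bound_rule": "R7",
          "kind": "row",
          "label": "participant number",
          "provenance": "default",
          "widget_config": {
            "active": true,
            "value_type": "text"
          }
        },
        {
          "bound_rule": "R8",
          "kind": "sub_tabs",
          "label": "Demographics",
          "provenance": "gui-rule-1",
          "widget_config": {
            "active": true,
            "target_collection": "C3"
          }
        }
      ],
      "label": "Patient ID",
      "provenance": "default",
      "sub_tabs": [
        {
          "collection": "C3",
          "components": [
            {
              "bound_rule": "R12",
              "kind": "text_field",
              "label": "name",
              "provenance": "gui-rule-2",
              "widget_config": {
                "active": true,
                "value_type": "text"
              }
            },
            {
              "bound_rule": "R13",
              "kind": "options_field",
              "label": "gender",
              "provenance": "gui-rule-3",
              "widget_config": {
                "active": true,
                "options": [
                  "female",
                  "male"
                ],
                "value_type": "text"
              }
            },
            {
              "bound_rule": "R14",
              "kind": "date_field",
              "label": "date of birth",
              "provenance": "gui-rule-4",
              "widget_config": {
                "active": true,
                "date_format": "YYYY-MM-DD",
                "value_type": "date"
              }
            },
            {
              "bound_rule": "R15",
              "kind": "options_field",
              "label": "smoking status",
              "provenance": "gui-rule-5",
              "widget_config": {
                "active": true,
                "options": [
                  "former smoker",
                  "non-smoker",
                  "smoker"
                ],
                "value_type": "text"
              }
            }
          ],
          "label": "Demographics",
          "provenance": "default",
          "sub_tabs": []
        },
        {
          "collection": "C4",
          "components": [
            {
              "bound_rule": "R16",
              "kind": "options_field",
              "label": "tumor grade",
              "provenance": "gui-rule-6",
              "widget_config": {
                "active": true,
                "options": [
                  "G1 well differentiated",
                  "G2 moderately differentiated",
                  "G3 poorly differentiated"
                ],
                "value_type": "text"
              }
            },
            {
              "bound_rule": "R17",
              "kind": "options_field",
              "label": "tumor type",
              "provenance": "gui-rule-7",
              "widget_config": {
                "active": true,
                "options": [
                  "adenocarcinoma",
                  "squamous cell"
                ],
                "value_type": "text"
              }
            }
          ],
          "label": "Histology",
          "provenance": "default",
          "sub_tabs": []
        },
        {
          "collection": "C5",
          "components": [
            {
              "bound_rule": "R18",
              "kind": "options_field",
              "label": "sample type",
              "provenance": "gui-rule-8",
              "widget_config": {
                "active": true,
                "options": [
                  "biopsy",
                  "blood",
                  "resection"
                ],
                "value_type": "text"
              }
            },
            {
              "bound_rule": "R19",
              "kind": "date_field",
              "label": "collection date",
              "provenance": "gui-rule-9",
              "widget_config": {
                "active": true,
                "date_format": "YYYY-MM-DD",
                "value_type": "date"
              }
            },
            {
              "bound_rule": "R20",
              "kind": "inactive_field",
              "label": "storage location",
              "provenance": "gui-rule-10",
              "widget_config": {
                "active": false,
                "value_type": "text"
              }
            }
          ],
          "label": "Tissue",
          "provenance": "default",
          "sub_tabs": []
        },
        {
          "collection": "C6",
          "components": [
            {
              "bound_rule": "R21",
              "kind": "options_field",
              "label": "regimen",
              "provenance": "gui-rule-11",
              "widget_config": {
                "active": true,
                "options": [
                  "DCF",
                  "ECF",
                  "FOLFOX"
                ],
                "value_type": "text"
              }
            },
            {
              "bound_rule": "R22",
              "kind": "row",
              "label": "cycles",
              "provenance": "default",
              "widget_config": {
                "active": true,
                "value_type": "number"
              }
            },
            {
              "bound_rule": "R23",
              "kind": "formula_field",
              "label": "dose",
              "provenance": "gui-rule-12",
              "widget_config": {
                "active": true,
                "formula": "{cycles} * 25",
                "value_type": "number"
              }
            }
          ],
          "label": "Treatment",
          "provenance": "default",
          "sub_tabs": []
        }
      ]
    }
  ],
  "triggers": []
}
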