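{
  "description": "Published data partitions (calibration/validation/test counts) and SPA-selected wavelengths per cultivar and stress experiment. DS = drought stress, TS = temperature stress, EWS = excessive water stress.",
  "experiments": {
    "DS_Jopung": {
      "n_selected": 23, "cal": 2070, "val": 690, "test": 690,
      "wavelengths_nm": [564.6, 594.9, 699.9, 702, 716.1, 728.2, 740.4, 748.4, 758.5, 766.6, 770.7, 782.8, 821.2, 831.3, 833.3, 837.4, 839.4, 853.5, 859.6, 863.6, 873.7, 879.8, 881.8]
    },
    "DS_Superior": {
      "n_selected": 24, "cal": 1865, "val": 621, "test": 622,
      "wavelengths_nm": [564.6, 594.9, 699.9, 702, 732.3, 742.4, 750.5, 754.5, 758.5, 782.8, 796.9, 809.1, 819.2, 823.2, 825.2, 829.3, 833.3, 841.4, 843.4, 855.5, 859.6, 873.7, 879.8, 885.9]
    },
    "DS_Jopung_Superior": {
      "n_selected": 27, "cal": 3935, "val": 1312, "test": 1311,
      "wavelengths_nm": [564.6, 594.9, 699.9, 702, 714.1, 734.3, 742.4, 746.4, 750.5, 754.5, 758.5, 762.6, 766.6, 778.8, 782.8, 786.8, 796.9, 809.1, 821.2, 823.2, 829.3, 833.3, 839.4, 853.5, 855.5, 873.7, 896]
    },
    "TS_Jopung": {
      "n_selected": 31, "cal": 2848, "val": 949, "test": 949,
      "wavelengths_nm": [556.5, 564.6, 568.6, 617.1, 627.2, 659.5, 671.7, 693.9, 708, 724.2, 728.2, 746.4, 764.6, 766.6, 799, 801, 803, 815.1, 821.2, 825.2, 833.3, 843.4, 859.6, 869.7, 873.7, 875.8, 879.8, 881.8, 883.8, 887.9, 896]
    },
    "TS_Superior": {
      "n_selected": 32, "cal": 2385, "val": 795, "test": 795,
      "wavelengths_nm": [516.1, 556.5, 564.6, 576.7, 617.1, 619.1, 627.2, 649.4, 659.5, 671.7, 675.7, 693.9, 710.1, 744.4, 748.4, 760.6, 772.7, 778.8, 780.8, 809.1, 821.2, 823.2, 843.4, 845.4, 847.5, 857.6, 859.6, 885.9, 887.9, 893.9, 896, 898]
    },
    "TS_Jopung_Superior": {
      "n_selected": 25, "cal": 5228, "val": 1743, "test": 1743,
      "wavelengths_nm": [556.5, 564.6, 576.7, 617.1, 619.1, 627.2, 659.5, 671.7, 675.7, 693.9, 708, 710.1, 742.4, 768.7, 817.2, 821.2, 827.3, 829.3, 833.3, 843.4, 845.4, 853.5, 855.5, 883.8, 891.9]
    },
    "DS_Jinyulmi": {
      "n_selected": 32, "cal": 3870, "val": 1290, "test": 1290,
      "wavelengths_nm": [603, 613.1, 631.2, 671.7, 724.2, 770.7, 776.7, 778.8, 780.8, 782.8, 784.8, 786.8, 788.9, 790.9, 796.9, 803, 805, 807, 809.1, 819.2, 823.2, 847.5, 851.5, 853.5, 857.6, 861.6, 863.6, 865.6, 871.7, 881.8, 883.8, 893.9]
    },
    "EWS_Jinyulmi": {
      "n_selected": 21, "cal": 3576, "val": 1192, "test": 1192,
      "wavelengths_nm": [625.2, 637.3, 655.5, 665.6, 728.2, 736.3, 742.4, 746.4, 752.5, 764.6, 768.7, 782.8, 794.9, 796.9, 813.1, 815.1, 823.2, 863.6, 871.7, 875.8, 877.8]
    }
  }
}
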