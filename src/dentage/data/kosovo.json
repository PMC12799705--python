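{"population": "kosovo", "score_table": {"F": {"31": {"D": 5.20, "E": 6.60, "F": 6.70, "G": 7.70, "H": 12.20}, "32": {"D": 5.00, "E": 6.60, "F": 7.40, "G": 8.70, "H": 12.70}, "33": {"B": 5.50, "C": 6.10, "D": 7.90, "E": 8.70, "F": 10.10, "G": 12.10, "H": 14.10}, "34": {"B": 4.80, "C": 7.40, "D": 8.30, "E": 9.70, "F": 11.00, "G": 12.10, "H": 14.30}, "35": {"A": 5.00, "B": 6.50, "C": 8.00, "D": 9.10, "E": 10.20, "F": 11.60, "G": 12.60, "H": 14.70}, "36": {"E": 5.90, "F": 5.80, "G": 8.50, "H": 12.60}, "37": {"A": 4.90, "B": 7.40, "C": 8.30, "D": 9.50, "E": 10.60, "F": 12.00, "G": 13.30, "H": 15.30}}, "M": {"31": {"E": 8.40, "F": 7.80, "G": 8.70, "H": 12.60}, "32": {"D": 8.40, "E": 7.10, "F": 8.20, "G": 9.20, "H": 13.10}, "33": {"C": 7.90, "D": 7.40, "E": 8.00, "F": 10.60, "G": 13.20, "H": 14.80}, "34": {"C": 7.20, "D": 7.50, "E": 9.30, "F": 11.10, "G": 12.50, "H": 14.60}, "35": {"B": 8.50, "C": 7.40, "D": 8.20, "E": 9.70, "F": 11.60, "G": 13.50, "H": 14.80}, "36": {"E": 5.40, "F": 7.30, "G": 9.10, "H": 12.90}, "37": {"B": 8.70, "C": 7.70, "D": 9.50, "E": 10.70, "F": 12.30, "G": 14.20, "H": 15.20}}}, "conversion": {"F": [[6.00, 48.06], [6.10, 48.89], [6.20, 49.73], [6.30, 50.57], [6.40, 51.40], [6.50, 52.24], [6.60, 53.07], [6.70, 53.91], [6.80, 54.74], [6.90, 55.56], [7.00, 56.39], [7.10, 57.21], [7.20, 58.03], [7.30, 58.84], [7.40, 59.65], [7.50, 60.45], [7.60, 61.25], [7.70, 62.04], [7.80, 62.82], [7.90, 63.60], [8.00, 64.37], [8.10, 65.14], [8.20, 65.89], [8.30, 66.64], [8.40, 67.38], [8.50, 68.11], [8.60, 68.83], [8.70, 69.55], [8.80, 70.25], [8.90, 70.95], [9.00, 71.63], [9.10, 72.31], [9.20, 72.97], [9.30, 73.63], [9.40, 74.27], [9.50, 74.91], [9.60, 75.53], [9.70, 76.14], [9.80, 76.75], [9.90, 77.34], [10.00, 77.92], [10.10, 78.49], [10.20, 79.05], [10.30, 79.60], [10.40, 80.14], [10.50, 80.66], [10.60, 81.18], [10.70, 81.69], [10.80, 82.18], [10.90, 82.67], [11.00, 83.14], [11.10, 83.60], [11.20, 84.06], [11.30, 84.50], [11.40, 84.93], [11.50, 85.36], [11.60, 85.77], [11.70, 86.17], [11.80, 86.57], [11.90, 86.95], [12.00, 87.33], [12.10, 87.69], [12.20, 88.05], [12.30, 88.40], [12.40, 88.74], [12.50, 89.07], [12.60, 89.39], [12.70, 89.70], [12.80, 90.01], [12.90, 90.30], [13.00, 90.59], [13.10, 90.87], [13.20, 91.15], [13.30, 91.41], [13.40, 91.67], [13.50, 91.93], [13.60, 92.17], [13.70, 92.41], [13.80, 92.64], [13.90, 92.86], [14.00, 93.08], [14.10, 93.30], [14.20, 93.50], [14.30, 93.70], [14.40, 93.90], [14.50, 94.09], [14.60, 94.27], [14.70, 94.45], [14.80, 94.62], [14.90, 94.79], [15.00, 94.95], [15.10, 95.11], [15.20, 95.26], [15.30, 95.41], [15.40, 95.56], [15.50, 95.70], [15.60, 95.83], [15.70, 95.96], [15.80, 96.09], [15.90, 96.21], [16.00, 96.33]], "M": [[6.00, 45.46], [6.10, 46.41], [6.20, 47.37], [6.30, 48.34], [6.40, 49.30], [6.50, 50.27], [6.60, 51.23], [6.70, 52.19], [6.80, 53.15], [6.90, 54.11], [7.00, 55.07], [7.10, 56.02], [7.20, 56.97], [7.30, 57.91], [7.40, 58.85], [7.50, 59.78], [7.60, 60.70], [7.70, 61.62], [7.80, 62.53], [7.90, 63.43], [8.00, 64.32], [8.10, 65.20], [8.20, 66.07], [8.30, 66.93], [8.40, 67.77], [8.50, 68.61], [8.60, 69.43], [8.70, 70.25], [8.80, 71.05], [8.90, 71.83], [9.00, 72.61], [9.10, 73.37], [9.20, 74.11], [9.30, 74.85], [9.40, 75.57], [9.50, 76.27], [9.60, 76.96], [9.70, 77.64], [9.80, 78.30], [9.90, 78.95], [10.00, 79.58], [10.10, 80.20], [10.20, 80.81], [10.30, 81.40], [10.40, 81.98], [10.50, 82.54], [10.60, 83.09], [10.70, 83.62], [10.80, 84.14], [10.90, 84.65], [11.00, 85.15], [11.10, 85.63], [11.20, 86.10], [11.30, 86.55], [11.40, 86.99], [11.50, 87.42], [11.60, 87.84], [11.70, 88.25], [11.80, 88.64], [11.90, 89.02], [12.00, 89.40], [12.10, 89.76], [12.20, 90.10], [12.30, 90.44], [12.40, 90.77], [12.50, 91.09], [12.60, 91.40], [12.70, 91.70], [12.80, 91.98], [12.90, 92.26], [13.00, 92.54], [13.10, 92.80], [13.20, 93.05], [13.30, 93.30], [13.40, 93.53], [13.50, 93.76], [13.60, 93.98], [13.70, 94.20], [13.80, 94.41], [13.90, 94.61], [14.00, 94.80], [14.10, 94.99], [14.20, 95.17], [14.30, 95.34], [14.40, 95.51], [14.50, 95.67], [14.60, 95.83], [14.70, 95.98], [14.80, 96.13], [14.90, 96.27], [15.00, 96.40], [15.10, 96.54], [15.20, 96.66], [15.30, 96.78], [15.40, 96.90], [15.50, 97.02], [15.60, 97.13], [15.70, 97.23], [15.80, 97.33], [15.90, 97.43], [16.00, 97.53]]}}
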